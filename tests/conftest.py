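"""Shared fixtures: small synthetic cohorts and (session-scoped) the scaled
study replica used by the end-to-end recovery checks."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import eegpls as e
from eegpls.pipeline import scaled_study_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_config(seed: int = 3) -> e.AnalysisConfig:
    """A deliberately minimal study configuration for fast pipeline tests."""
    design = e.CohortDesign(
        n_per_group={"responder": 3, "nonresponder": 2},
        epochs_per_recording=(4, 6),
        channel_labels=("F3", "F4", "P3", "P4"),
        seed=seed,
    )
    effects = [
        e.EffectSpec("wpli", ("F3", "P3"), freq=10.0, state="EC", profile={
            ("responder", "baseline"): 0.5, ("responder", "week1"): 0.5,
            ("responder", "week12"): 0.0,
            ("nonresponder", "baseline"): 0.0, ("nonresponder", "week1"): 0.0,
            ("nonresponder", "week12"): 0.5,
        }),
        e.EffectSpec("mse", ("F3", "F4", "P3", "P4"), state="EO", profile={
            ("responder", "baseline"): 0.35, ("responder", "week1"): 0.05,
            ("responder", "week12"): 0.0,
        }),
    ]
    from eegpls import connectivity as conn
    return e.AnalysisConfig(
        design=design,
        effects=effects,
        fourier_grid=conn.fourier_grid(4.0, 20.0, 0.5),
        morlet_grid=conn.morlet_grid(6.0, 20.0, 2.0),
        pls=e.PLSSettings(n_perm=30, n_boot=15),
        seed=seed,
    )


@pytest.fixture(scope="session")
def replica():
    """The scaled study replica, run once per test session.

    Covers group recovery, BSR stability, and group-to-individual
    generalizability checks at the reduced (12+9 participant) scale.
    """
    return e.run_study(scaled_study_config(seed=7))


@pytest.fixture(scope="session")
def coupled_recording():
    """25-epoch two-channel recording with a pi/4-lag 10 Hz shared
    oscillator over unit background noise."""
    design = e.CohortDesign(n_per_group={"responder": 2, "nonresponder": 2},
                            channel_labels=("A", "B"))
    rng = np.random.default_rng(99)
    from eegpls.cohort import OscillatorSpec, synthesize_epoch
    data = np.array([
        synthesize_epoch([OscillatorSpec(10.0, 0.5, {0: 0.0, 1: np.pi / 4})],
                         1000, 500.0, rng, 2, 0.5, 0.5)
        for _ in range(25)
    ])
    return e.EpochedRecording("p1", "responder", "baseline", "EC", 30.0,
                              data, 500.0, ("A", "B"))
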