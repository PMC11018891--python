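"""Synthetic resting-state EEG cohort generator.

Builds epoched, multichannel EEG-like recordings for a two-group
(responder / non-responder), three-session (baseline, week 1, week 12)
longitudinal design with eyes-open / eyes-closed states, with *known*
connectivity and complexity structure injected per (group, session) cell.

The signal model is shared-oscillator-plus-independent-noise: each channel
is a mixture of 1/f ("pink") noise, white noise, and optionally one or more
sinusoidal oscillators shared between a set of channels with fixed, nonzero
channel-to-channel phase offsets.  Phase-lag consistency — the quantity the
weighted phase lag index measures — is therefore controlled in closed form
by the oscillator amplitude, while the white/pink mixing weights control the
scale profile of sample entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DEFAULT_CHANNELS",
    "SESSIONS",
    "STATES",
    "AgeModel",
    "CohortDesign",
    "EffectSpec",
    "OscillatorSpec",
    "EpochedRecording",
    "GroundTruth",
    "pink_noise",
    "synthesize_epoch",
    "generate_cohort",
]

#: 28-channel montage used throughout (10-20 variant).
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "FC1", "FC2", "FC5", "FC6",
    "C3", "C4", "CP1", "CP2", "CP5", "CP6", "P3", "P4", "P7", "P8",
    "T7", "T8", "O1", "O2", "Fz", "Cz", "Pz", "Oz",
)

SESSIONS = ("baseline", "week1", "week12")
STATES = ("EC", "EO")
GROUPS = ("responder", "nonresponder")


@dataclass(frozen=True)
class AgeModel:
    """Per-group Normal age model, truncated to [low, high] years.

    The responder mean is set below the non-responder mean so that age is
    correlated with group and the confound-regression stage is exercised.
    """

    mean: Mapping[str, float] = field(
        default_factory=lambda: {"responder": 35.1, "nonresponder": 44.8}
    )
    sd: Mapping[str, float] = field(
        default_factory=lambda: {"responder": 10.5, "nonresponder": 11.5}
    )
    low: float = 18.0
    high: float = 65.0

    def draw(self, group: str, rng: np.random.Generator) -> float:
        for _ in range(1000):
            a = rng.normal(self.mean[group], self.sd[group])
            if self.low <= a <= self.high:
                return float(a)
        return float(np.clip(self.mean[group], self.low, self.high))


@dataclass
class CohortDesign:
    """Structural parameters of the simulated study."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"responder": 25, "nonresponder": 18}
    )
    sessions: Sequence[str] = SESSIONS
    states: Sequence[str] = STATES
    epochs_per_recording: tuple[int, int] = (63, 113)
    sampling_rate: float = 500.0
    epoch_length: float = 2.0
    channel_labels: Sequence[str] = DEFAULT_CHANNELS
    age_model: AgeModel = field(default_factory=AgeModel)
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.epoch_length))

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def validate(self) -> None:
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValueError("need at least 2 participants per group")
        n = self.sampling_rate * self.epoch_length
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("sampling_rate * epoch_length must be a positive integer")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        lo, hi = self.epochs_per_recording
        if not (1 <= lo <= hi):
            raise ValueError("invalid epochs_per_recording range")


@dataclass
class EffectSpec:
    """One injectable (group x session) effect.

    For ``feature_kind == "wpli"`` the effect is a shared oscillator at
    ``freq`` Hz on ``channels``, with channel-to-channel phase offsets spaced
    by ``phase_lag`` radians; ``profile[(group, session)]`` is the oscillator
    amplitude relative to unit-SD background noise.

    For ``feature_kind == "mse"`` the effect shifts the pink-noise fraction of
    ``channels`` by ``profile[(group, session)]``; a larger pink fraction
    raises coarse-scale and lowers fine-scale sample entropy.
    """

    feature_kind: str  # "wpli" | "mse"
    channels: Sequence[str]
    profile: Mapping[tuple[str, str], float]
    freq: float | None = None  # Hz, wpli only
    phase_lag: float = np.pi / 4
    state: str | None = None  # None = applies to all states

    def validate(self, design: CohortDesign) -> None:
        if self.feature_kind not in ("wpli", "mse"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        missing = set(self.channels) - set(design.channel_labels)
        if missing:
            raise ValueError(f"effect channels not in design montage: {missing}")
        if self.feature_kind == "wpli":
            if self.freq is None or not self.freq < design.sampling_rate / 2:
                raise ValueError("wpli effect needs a frequency below Nyquist")
            if abs(np.sin(self.phase_lag)) < 1e-9:
                raise ValueError("phase_lag must avoid 0 and pi (mod pi)")
        for v in self.profile.values():
            if not np.isfinite(v):
                raise ValueError("non-finite effect magnitude")


@dataclass
class OscillatorSpec:
    """One shared sinusoid: frequency, amplitude, per-channel phase offsets."""

    freq: float
    amplitude: float
    channel_phase: Mapping[int, float]  # channel index -> phase offset (rad)


@dataclass
class EpochedRecording:
    """One participant/session/state recording: epochs x channels x samples."""

    participant_id: str
    group: str
    session: str
    state: str
    age: float
    data: np.ndarray
    sampling_rate: float
    channel_labels: Sequence[str]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if np.any(self.data.std(axis=2) <= 0):
            raise ValueError("zero-variance epoch/channel")


@dataclass
class GroundTruth:
    """Generator bookkeeping: which pattern each participant was given."""

    pattern_labels: dict[str, str]  # pid -> "own-group" | "opposite"
    groups: dict[str, str]  # pid -> group label
    ages: dict[str, float]
    effects: list[EffectSpec]
    seed: int

    def to_json(self) -> str:
        d = {
            "pattern_labels": self.pattern_labels,
            "groups": self.groups,
            "ages": self.ages,
            "effects": [
                {**asdict(e), "profile": {f"{g}|{s}": v for (g, s), v in e.profile.items()}}
                for e in self.effects
            ],
            "seed": self.seed,
        }
        return json.dumps(d, sort_keys=True, indent=1)


def pink_noise(n_samples: int, rng: np.random.Generator, n_channels: int = 1) -> np.ndarray:
    """1/f-amplitude noise, unit SD per channel, shape (n_channels, n_samples)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    f[0] = f[1]  # avoid division by zero at DC
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = out.std(axis=1, keepdims=True)
    return out / np.where(sd > 0, sd, 1.0)


def synthesize_epoch(
    oscillators: Sequence[OscillatorSpec],
    n_samples: int,
    sampling_rate: float,
    rng: np.random.Generator,
    n_channels: int,
    pink_weight: np.ndarray | float = 0.5,
    white_weight: np.ndarray | float = 0.5,
    common_zero_lag: float = 0.0,
) -> np.ndarray:
    """Synthesize one epoch, channels x samples.

    Each channel is the sum of the shared sinusoids it participates in (with
    its channel-specific phase offset and a per-epoch random common phase),
    independent 1/f noise, and independent white noise.  ``common_zero_lag``
    adds an identical pink-noise source to every channel (a volume-conduction
    stressor: zero phase lag everywhere).
    """
    if n_samples < 1:
        raise ValueError("zero-length epoch")
    for osc in oscillators:
        if osc.freq >= sampling_rate / 2:
            raise ValueError(f"oscillator at {osc.freq} Hz >= Nyquist")
    pink_w = np.broadcast_to(np.asarray(pink_weight, dtype=float), (n_channels,))
    white_w = np.broadcast_to(np.asarray(white_weight, dtype=float), (n_channels,))

    t = np.arange(n_samples) / sampling_rate
    data = pink_w[:, None] * pink_noise(n_samples, rng, n_channels)
    data = data + white_w[:, None] * rng.standard_normal((n_channels, n_samples))
    for osc in oscillators:
        phi0 = rng.uniform(0.0, 2 * np.pi)  # common phase, random per epoch
        for ch, off in osc.channel_phase.items():
            data[ch] += osc.amplitude * np.sin(2 * np.pi * osc.freq * t + phi0 + off)
    if common_zero_lag != 0.0:
        data += common_zero_lag * pink_noise(n_samples, rng, 1)
    return data


def _participant_ids(design: CohortDesign) -> list[tuple[str, str]]:
    out = []
    for g in design.n_per_group:
        tag = "R" if g == "responder" else "N"
        for i in range(design.n_per_group[g]):
            out.append((f"{tag}{i + 1:02d}", g))
    return out


def generate_cohort(
    design: CohortDesign,
    effects: Sequence[EffectSpec],
    deviant_fraction: float = 0.0,
    base_pink_fraction: float = 0.5,
    common_zero_lag: float = 0.0,
) -> tuple[list[EpochedRecording], GroundTruth]:
    """Generate one recording per participant x session x state.

    ``deviant_fraction`` of each group's participants (rounded, seeded
    assignment) receive the *opposite* group's effect profiles, emulating
    individual deviation from the group pattern; ground truth records who.
    """
    design.validate()
    for e in effects:
        e.validate(design)
    if not 0.0 <= deviant_fraction <= 1.0:
        raise ValueError("deviant_fraction must be in [0, 1]")

    root = np.random.SeedSequence(design.seed)
    ss_assign, ss_age, ss_data = root.spawn(3)
    rng_assign = np.random.Generator(np.random.PCG64(ss_assign))
    rng_age = np.random.Generator(np.random.PCG64(ss_age))

    pids = _participant_ids(design)
    labels: dict[str, str] = {}
    for g in design.n_per_group:
        members = [p for p, gg in pids if gg == g]
        n_dev = int(round(deviant_fraction * len(members)))
        dev = set(rng_assign.choice(members, size=n_dev, replace=False)) if n_dev else set()
        for p in members:
            labels[p] = "opposite" if p in dev else "own-group"

    ages = {p: design.age_model.draw(g, rng_age) for p, g in pids}
    ch_index = {c: i for i, c in enumerate(design.channel_labels)}
    other = {"responder": "nonresponder", "nonresponder": "responder"}

    recordings: list[EpochedRecording] = []
    data_children = ss_data.spawn(len(pids))
    for (pid, group), child in zip(pids, data_children):
        eff_group = other[group] if labels[pid] == "opposite" else group
        per_rec = child.spawn(len(design.sessions) * len(design.states))
        k = 0
        for session in design.sessions:
            for state in design.states:
                rng = np.random.Generator(np.random.PCG64(per_rec[k]))
                k += 1
                n_ep = int(rng.integers(design.epochs_per_recording[0],
                                        design.epochs_per_recording[1] + 1))
                oscillators = []
                pink_w = np.full(design.n_channels, base_pink_fraction)
                for e in effects:
                    if e.state is not None and e.state != state:
                        continue
                    mag = e.profile.get((eff_group, session), 0.0)
                    idx = [ch_index[c] for c in e.channels]
                    if e.feature_kind == "wpli":
                        if mag != 0.0:
                            phases = {c: j * e.phase_lag for j, c in enumerate(idx)}
                            oscillators.append(OscillatorSpec(e.freq, mag, phases))
                    else:  # mse: shift the pink fraction
                        pink_w[idx] = np.clip(pink_w[idx] + mag, 0.05, 0.95)
                white_w = 1.0 - pink_w
                epochs = np.empty((n_ep, design.n_channels, design.n_samples))
                for ep in range(n_ep):
                    epochs[ep] = synthesize_epoch(
                        oscillators, design.n_samples, design.sampling_rate, rng,
                        design.n_channels, pink_w, white_w, common_zero_lag,
                    )
                rec = EpochedRecording(pid, group, session, state, ages[pid],
                                       epochs, design.sampling_rate,
                                       tuple(design.channel_labels))
                rec.validate()
                recordings.append(rec)

    truth = GroundTruth(labels, dict(pids), ages, list(effects), design.seed)
    return recordings, truth
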