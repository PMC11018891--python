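"""End-to-end study orchestration.

Flow: simulate (or load) a cohort -> connectivity / complexity features ->
group mean-centered PLS-SVD (omnibus 2-group x 3-session, per-group
follow-ups when the omnibus LV expresses a group x session interaction) ->
single-participant non-rotated PLS against the predefined session contrasts
-> group-to-individual similarity summary.

Connectivity group analyses run twice: on across-epoch (Fourier) WPLI, and
on epoch-averaged within-epoch (Morlet) WPLI; the latter lives on the same
grid as the single-epoch individual analyses and is therefore the source of
the group patterns used for similarity scoring.  By default WPLI analyses
use the eyes-closed state and MSE analyses the eyes-open state (the states
with the strongest effects), each state analyzed separately.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import connectivity as conn
from . import complexity as cplx
from .cohort import CohortDesign, EffectSpec, EpochedRecording, generate_cohort
from .features import (FeatureMatrix, assemble_group_matrix,
                       assemble_individual_matrix, mse_column_metadata,
                       regress_out_age, wpli_column_metadata)
from .io import results_json
from .pls import Contrast, LatentVariable, group_pls, nonrotated_pls
from .similarity import (RatingRules, RuleWindow, SimilarityRecord,
                         assess_individual, extract_group_pattern,
                         rating_category, rule_based_rating, summarize_cohort)

__all__ = [
    "PLSSettings",
    "AnalysisConfig",
    "interaction_share",
    "run_study",
    "scaled_study_config",
    "WPLI_CONTRAST",
    "MSE_CONTRASTS",
]

#: Week-1 -> week-12 change contrast used for individual connectivity
#: analyses (direction and frequencies left to the data).
WPLI_CONTRAST = Contrast((0.0, 1.0, -1.0), label="week1_vs_week12")

#: Predefined complexity contrasts: linear change (responder pattern) and
#: late-only change (non-responder pattern).
MSE_CONTRASTS = {
    "responder": Contrast((1.0, 0.0, -1.0), label="linear"),
    "nonresponder": Contrast((1.0, 1.0, -2.0), label="late_change"),
}


@dataclass(frozen=True)
class PLSSettings:
    n_perm: int = 500
    n_boot: int = 200
    alpha: float = 0.05
    followup_alpha: float = 0.025  # Bonferroni over the two per-group tests
    strict_alpha: float = 0.001
    bsr_stable: float = 2.0
    bsr_strict: float = 3.1
    interaction_share_min: float = 0.1

    def __post_init__(self):
        for a in (self.alpha, self.followup_alpha, self.strict_alpha):
            if not 0 < a < 1:
                raise ValueError("alphas must lie in (0, 1)")


def default_wpli_rules() -> RatingRules:
    """Visual-rating analogue for connectivity: with the (0 1 -1) contrast a
    positive loading means a week-1 -> week-12 decrease."""
    return RatingRules(
        responder_windows=(
            RuleWindow("alpha_decrease", {"frequency": (8.0, 14.0)}, +1),
            RuleWindow("beta_increase", {"frequency": (18.0, 30.0)}, -1),
        ),
        nonresponder_windows=(
            RuleWindow("alpha_increase", {"frequency": (8.0, 14.0)}, -1),
            RuleWindow("beta_decrease", {"frequency": (18.0, 30.0)}, +1),
        ),
    )


def default_mse_rules() -> RatingRules:
    """Visual-rating analogue for complexity: responder = early coarse-scale
    decrease on the linear-contrast LV; non-responder = late-only coarse-
    scale change on the late-change LV."""
    return RatingRules(
        responder_windows=(
            RuleWindow("early_coarse_decrease", {"lv": "linear", "scale": (10, 20)},
                       +1, timing=("early_change", 0.5)),
        ),
        nonresponder_windows=(
            RuleWindow("late_coarse_change", {"lv": "late_change", "scale": (10, 20)},
                       +1, timing=("no_early_change", 0.5)),
        ),
    )


@dataclass
class AnalysisConfig:
    design: CohortDesign
    effects: Sequence[EffectSpec] = ()
    deviant_fraction: float = 0.0
    state_for: Mapping[str, str] = field(
        default_factory=lambda: {"wpli": "EC", "mse": "EO"})
    fourier_grid: conn.FrequencyGrid = field(default_factory=conn.fourier_grid)
    morlet_grid: conn.FrequencyGrid = field(default_factory=conn.morlet_grid)
    mse_params: cplx.MSEParams = field(default_factory=cplx.MSEParams)
    pls: PLSSettings = field(default_factory=PLSSettings)
    wpli_rules: RatingRules = field(default_factory=default_wpli_rules)
    mse_rules: RatingRules = field(default_factory=default_mse_rules)
    seed: int = 0

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return {k: enc(v) for k, v in vars(o).items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, Mapping):
                return {str(k): enc(v) for k, v in o.items()}
            return repr(o)
        payload = json.dumps(enc(self), sort_keys=True, default=repr)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def interaction_share(saliences: np.ndarray, n_groups: int, n_conds: int) -> float:
    """Fraction of a salience vector's norm carried by the group x condition
    interaction component (two-way decomposition of the reshaped cell grid).

    Zero for a single group (no interaction is definable).
    """
    if n_groups < 2:
        return 0.0
    M = np.asarray(saliences, dtype=float).reshape(n_groups, n_conds)
    grand = M.mean()
    rows = M.mean(axis=1, keepdims=True) - grand
    cols = M.mean(axis=0, keepdims=True) - grand
    inter = M - grand - rows - cols
    total = np.linalg.norm(M)
    return float(np.linalg.norm(inter) / total) if total > 0 else 0.0


def _lv_summary(lv: LatentVariable, settings: PLSSettings) -> dict:
    out = {
        "p": lv.p,
        "singular_value": lv.singular_value,
        "pcce": lv.pcce,
        "saliences": lv.saliences,
        "cells": ["|".join(map(str, c)) if isinstance(c, tuple) else str(c)
                  for c in lv.cell_labels],
        "condition_means": {"|".join(map(str, k)) if isinstance(k, tuple) else str(k): v
                            for k, v in (lv.condition_means or {}).items()},
        "condition_ci": {"|".join(map(str, k)) if isinstance(k, tuple) else str(k): v
                         for k, v in (lv.condition_ci or {}).items()},
    }
    if lv.bsr is not None:
        out["n_stable"] = int(np.sum(np.abs(lv.bsr) > settings.bsr_stable))
        out["n_strict_stable"] = int(np.sum(np.abs(lv.bsr) > settings.bsr_strict))
    return out


def _subset_group(fm: FeatureMatrix, group: str) -> FeatureMatrix:
    sel = (fm.rows["group"] == group).to_numpy()
    return FeatureMatrix(fm.values[sel], fm.rows[sel].reset_index(drop=True),
                         fm.cols, fm.provenance, dict(fm.extra))


def _run_group_block(fm: FeatureMatrix, settings: PLSSettings, seed) -> dict:
    """Omnibus PLS, interaction gate, per-group follow-ups."""
    from .pls import _seedseq
    s_omni, s_r, s_n = _seedseq(seed).spawn(3)
    groups = list(dict.fromkeys(fm.rows["group"]))
    conds = list(dict.fromkeys(fm.rows["session"]))
    lvs = group_pls(fm, n_perm=settings.n_perm, n_boot=settings.n_boot, seed=s_omni)
    lv1 = lvs[0]
    share = interaction_share(lv1.saliences, len(groups), len(conds))
    gate = lv1.p < settings.alpha and share > settings.interaction_share_min
    block = {
        "omnibus": {"lvs": lvs, "interaction_share": share, "gate": gate},
        "followups": {},
    }
    if gate:
        for g, s_g in zip(groups, (s_r, s_n)):
            sub = _subset_group(fm, g)
            g_lvs = group_pls(sub, n_perm=settings.n_perm,
                              n_boot=settings.n_boot, seed=s_g)
            block["followups"][g] = {
                "lvs": g_lvs,
                "significant": g_lvs[0].p < settings.followup_alpha,
            }
    return block


def run_study(config: AnalysisConfig) -> dict:
    """Run the full study and return a results bundle.

    The bundle's ``"json"`` entry is a deterministic serializable summary
    (identical configs give byte-identical JSON via
    :func:`eegpls.io.results_json`); richer objects (LVs, feature matrices,
    similarity records) are kept under their own keys for programmatic use.
    """
    design = config.design
    root = np.random.SeedSequence(config.seed)
    ss_cohort, ss_wpli_f, ss_wpli_m, ss_mse, ss_indiv = root.spawn(5)
    design = replace(design, seed=int(ss_cohort.generate_state(1)[0] % (2 ** 31)))

    recordings, truth = generate_cohort(design, config.effects,
                                        deviant_fraction=config.deviant_fraction)
    by_key: dict[tuple, EpochedRecording] = {
        (r.participant_id, r.session, r.state): r for r in recordings}
    participants = [(p, g) for p, g in truth.groups.items()]
    # keep group-major order as generated
    log = {"epochs": {}, "wpli_denominator_zero": 0, "mse_undefined": 0}

    # ---- features -------------------------------------------------------
    st_w, st_m = config.state_for["wpli"], config.state_for["mse"]
    pairs = conn.enumerate_pairs(design.channel_labels)
    wpli_cols = wpli_column_metadata(config.fourier_grid, pairs)
    morlet_cols = wpli_column_metadata(config.morlet_grid, pairs)
    mse_cols = mse_column_metadata(design.channel_labels,
                                   np.arange(1, config.mse_params.max_scale + 1))

    fourier_maps, morlet_avg_maps, mse_avg_maps = {}, {}, {}
    morlet_epochs: dict[str, dict[str, list[np.ndarray]]] = {}
    mse_epochs: dict[str, dict[str, list[np.ndarray]]] = {}
    for pid, g in participants:
        morlet_epochs[pid], mse_epochs[pid] = {}, {}
        for session in design.sessions:
            rec_w = by_key[(pid, session, st_w)]
            rec_m = by_key[(pid, session, st_m)]
            log["epochs"][f"{pid}|{session}"] = int(rec_w.data.shape[0])

            cm = conn.wpli_across_epochs(rec_w, config.fourier_grid)
            log["wpli_denominator_zero"] += int(cm.denominator_zero.sum())
            fourier_maps[(pid, session)] = cm.values

            per_ep, avg = conn.wpli_single_epoch(rec_w, config.morlet_grid)
            morlet_avg_maps[(pid, session)] = avg.values
            morlet_epochs[pid][session] = [m.values for m in per_ep]

            mse_list, mse_avg = cplx.mse_for_recording(rec_m, config.mse_params)
            log["mse_undefined"] += int(sum(m.undefined.sum() for m in mse_list))
            mse_avg_maps[(pid, session)] = mse_avg.values
            mse_epochs[pid][session] = [np.nan_to_num(m.values) for m in mse_list]

    ages = truth.ages
    fm_fourier = regress_out_age(assemble_group_matrix(
        fourier_maps, participants, design.sessions, wpli_cols, ages))
    fm_morlet = regress_out_age(assemble_group_matrix(
        morlet_avg_maps, participants, design.sessions, morlet_cols, ages))
    fm_mse = regress_out_age(assemble_group_matrix(
        mse_avg_maps, participants, design.sessions, mse_cols, ages))

    # ---- group analyses -------------------------------------------------
    settings = config.pls
    group_results = {
        "wpli_fourier": _run_group_block(fm_fourier, settings, ss_wpli_f),
        "wpli_morlet_avg": _run_group_block(fm_morlet, settings, ss_wpli_m),
        "mse": _run_group_block(fm_mse, settings, ss_mse),
    }

    # ---- group patterns for similarity ---------------------------------
    patterns = {"wpli": {}, "mse": {}}
    src = {"wpli": ("wpli_morlet_avg", morlet_cols), "mse": ("mse", mse_cols)}
    for kind, (block_name, cols) in src.items():
        block = group_results[block_name]
        for g, fu in block["followups"].items():
            if fu["significant"]:
                contrast = WPLI_CONTRAST if kind == "wpli" else MSE_CONTRASTS[g]
                lv = fu["lvs"][0].align_to_contrast(contrast)
                try:
                    patterns[kind][g] = extract_group_pattern(
                        lv, settings.bsr_stable, group=g, cols=cols)
                except ValueError:
                    pass

    # ---- individual analyses -------------------------------------------
    indiv_children = ss_indiv.spawn(len(participants))
    records = {"wpli": [], "mse": []}
    indiv_json = {"wpli": {}, "mse": {}}
    for (pid, g), child in zip(participants, indiv_children):
        s_w, s_m1, s_m2 = child.spawn(3)
        # connectivity: single predefined contrast
        fm_i = assemble_individual_matrix(morlet_epochs[pid], design.sessions,
                                          morlet_cols, pid, group=g)
        lv_w = nonrotated_pls(fm_i, WPLI_CONTRAST, n_perm=settings.n_perm,
                              n_boot=settings.n_boot, seed=s_w)
        pat = patterns["wpli"].get(g)
        if pat is not None:
            rec = assess_individual(lv_w, pat, alpha=settings.alpha)
        else:
            rec = SimilarityRecord("", g, float(lv_w.p), False, None,
                                   "negligible_or_none",
                                   extra={"status": "not assessable"})
        rec.participant_id = pid
        fits_r, fits_n = rule_based_rating({"week1_vs_week12": lv_w},
                                           morlet_cols, config.wpli_rules,
                                           alpha=settings.alpha)
        rec.fits_responder_rule, rec.fits_nonresponder_rule = fits_r, fits_n
        rec.extra["p_strict"] = bool(lv_w.p < settings.strict_alpha)
        rec.extra["truth"] = truth.pattern_labels[pid]
        records["wpli"].append(rec)
        indiv_json["wpli"][pid] = {
            "group": g, "p": lv_w.p, "r": rec.r, "category": rec.category,
            "rating": rating_category(rec), "truth": truth.pattern_labels[pid],
        }

        # complexity: both predefined contrasts
        fm_im = assemble_individual_matrix(mse_epochs[pid], design.sessions,
                                           mse_cols, pid, group=g)
        lv_lin = nonrotated_pls(fm_im, MSE_CONTRASTS["responder"],
                                n_perm=settings.n_perm, n_boot=settings.n_boot,
                                seed=s_m1)
        lv_late = nonrotated_pls(fm_im, MSE_CONTRASTS["nonresponder"],
                                 n_perm=settings.n_perm, n_boot=settings.n_boot,
                                 seed=s_m2)
        own_lv = lv_lin if g == "responder" else lv_late
        pat = patterns["mse"].get(g)
        if pat is not None:
            rec = assess_individual(own_lv, pat, alpha=settings.alpha)
        else:
            rec = SimilarityRecord("", g, float(own_lv.p), False, None,
                                   "negligible_or_none",
                                   extra={"status": "not assessable"})
        rec.participant_id = pid
        fits_r, fits_n = rule_based_rating(
            {"linear": lv_lin, "late_change": lv_late}, mse_cols,
            config.mse_rules, alpha=settings.alpha)
        rec.fits_responder_rule, rec.fits_nonresponder_rule = fits_r, fits_n
        rec.extra["p_strict"] = bool(own_lv.p < settings.strict_alpha)
        rec.extra["truth"] = truth.pattern_labels[pid]
        records["mse"].append(rec)
        indiv_json["mse"][pid] = {
            "group": g, "p": own_lv.p, "r": rec.r, "category": rec.category,
            "rating": rating_category(rec), "truth": truth.pattern_labels[pid],
        }

    summaries = {kind: summarize_cohort(recs) for kind, recs in records.items()}

    # ---- serializable summary ------------------------------------------
    json_block = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_participants": len(participants),
        "log": log,
        "group": {
            name: {
                "omnibus_lv1": _lv_summary(block["omnibus"]["lvs"][0], settings),
                "interaction_share": block["omnibus"]["interaction_share"],
                "gate": block["omnibus"]["gate"],
                "followups": {
                    g: {"lv1": _lv_summary(fu["lvs"][0], settings),
                        "significant": fu["significant"]}
                    for g, fu in block["followups"].items()
                },
            }
            for name, block in group_results.items()
        },
        "individual": indiv_json,
        "similarity": summaries,
    }
    return {
        "config": config,
        "truth": truth,
        "features": {"wpli_fourier": fm_fourier, "wpli_morlet_avg": fm_morlet,
                     "mse": fm_mse},
        "group": group_results,
        "patterns": patterns,
        "records": records,
        "similarity": summaries,
        "json": json_block,
        "json_text": results_json(json_block),
    }


def scaled_study_config(seed: int = 0) -> AnalysisConfig:
    """A reduced study replica: same design logic at desk scale.

    12 responders / 9 non-responders, 10 channels (45 pairs), 20-30 epochs
    per recording, Fourier grid 2-30 Hz (0.5-Hz bins), Morlet grid 4-30 Hz
    (1-Hz steps).  Injected effects mirror the study findings: responders
    lose alpha (10 Hz) and gain beta (22 Hz) phase coupling from week 1 to
    week 12 with non-responders showing the opposite, and responders show an
    early widespread coarse-scale complexity decrease versus a late,
    spatially confined decrease in non-responders.
    """
    channels = ("Fp1", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2", "Fz")
    design = CohortDesign(
        n_per_group={"responder": 12, "nonresponder": 9},
        epochs_per_recording=(20, 30),
        channel_labels=channels,
        seed=seed,
    )
    alpha_set = ("F3", "C3", "P3", "O1")
    beta_set = ("F4", "C4", "P4", "O2")
    effects = [
        EffectSpec("wpli", alpha_set, freq=10.0, state="EC", profile={
            ("responder", "baseline"): 0.4, ("responder", "week1"): 0.4,
            ("responder", "week12"): 0.0,
            ("nonresponder", "baseline"): 0.0, ("nonresponder", "week1"): 0.0,
            ("nonresponder", "week12"): 0.4,
        }),
        EffectSpec("wpli", beta_set, freq=22.0, state="EC", profile={
            ("responder", "baseline"): 0.0, ("responder", "week1"): 0.0,
            ("responder", "week12"): 0.4,
            ("nonresponder", "baseline"): 0.4, ("nonresponder", "week1"): 0.4,
            ("nonresponder", "week12"): 0.0,
        }),
        EffectSpec("mse", channels, state="EO", profile={
            ("responder", "baseline"): 0.35, ("responder", "week1"): 0.05,
            ("responder", "week12"): 0.0,
        }),
        EffectSpec("mse", ("P3", "P4", "O1"), state="EO", profile={
            ("nonresponder", "baseline"): 0.3, ("nonresponder", "week1"): 0.3,
            ("nonresponder", "week12"): 0.0,
        }),
    ]
    return AnalysisConfig(
        design=design,
        effects=effects,
        deviant_fraction=0.1,
        fourier_grid=conn.fourier_grid(2.0, 30.0, 0.5),
        morlet_grid=conn.morlet_grid(4.0, 30.0, 1.0),
        seed=seed,
    )


def injected_element_masks(config: AnalysisConfig, cols) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth element masks for a connectivity feature grid.

    Returns ``(injected, null)`` boolean masks over the columns: *injected*
    elements are the coupled channel pairs at bins within 0.5 Hz of each
    effect's oscillator frequency; *null* elements exclude a 2 Hz guard band
    around each oscillator on its pairs (spectral leakage makes that
    neighbourhood neither cleanly signal nor cleanly noise).
    """
    f = cols["frequency"].to_numpy()
    ca = cols["channel_a"].to_numpy()
    cb = cols["channel_b"].to_numpy()
    injected = np.zeros(len(cols), dtype=bool)
    guard = np.zeros(len(cols), dtype=bool)
    for eff in config.effects:
        if eff.feature_kind != "wpli":
            continue
        chans = set(eff.channels)
        on_pair = np.array([a in chans and b in chans for a, b in zip(ca, cb)])
        injected |= on_pair & (np.abs(f - eff.freq) <= 0.5)
        guard |= on_pair & (np.abs(f - eff.freq) <= 2.0)
    return injected, ~guard
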