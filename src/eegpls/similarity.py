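"""Group-to-individual pattern similarity.

Quantifies how well each participant's single-participant (non-rotated) PLS
pattern reproduces the group-level singular image, two ways:

* **Correlation** — Pearson r between the group LV's element loadings,
  restricted to its stable elements (|BSR| > 2, ~95% CI), and the same
  elements of the individual's loadings.  Individuals whose own analysis is
  non-significant (p >= alpha) are recorded as showing no correlation with
  the group pattern.  Categories: r >= .4 moderate-strong, .1 < r < .4 weak
  positive, -.1 <= r <= .1 negligible, r < -.1 negative.
* **Rule-based rating** — a deterministic analogue of visual rating: signed,
  stable (|BSR| > 2) loadings are aggregated within predefined element
  windows (e.g. alpha 8-14 Hz decrease and/or beta 18-30 Hz increase for the
  responder connectivity pattern) and turned into fits-responder /
  fits-non-responder flags, yielding the four categories own-pattern-only,
  both, opposite-only, neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pls import LatentVariable

__all__ = [
    "GroupPattern",
    "SimilarityRecord",
    "RuleWindow",
    "RatingRules",
    "extract_group_pattern",
    "assess_individual",
    "categorize",
    "rule_based_rating",
    "rating_category",
    "summarize_cohort",
]

CATEGORIES = ("moderate_strong", "weak_positive", "negligible_or_none", "negative")
RATING_CATEGORIES = ("own_only", "both", "opposite_only", "neither")


@dataclass
class GroupPattern:
    """Stable part of a group LV's singular image."""

    loadings: np.ndarray  # restricted to the stable mask
    mask: np.ndarray  # bool over the full feature grid
    contrast_label: str
    group: str
    bsr_threshold: float
    cols: pd.DataFrame | None = None


@dataclass
class SimilarityRecord:
    participant_id: str
    group: str
    p: float
    contrast_matched: bool
    r: float | None
    category: str
    fits_responder_rule: bool | None = None
    fits_nonresponder_rule: bool | None = None
    extra: dict = field(default_factory=dict)


def extract_group_pattern(group_lv: LatentVariable, bsr_threshold: float = 2.0,
                          group: str = "", cols: pd.DataFrame | None = None,
                          min_elements: int = 10) -> GroupPattern:
    """Restrict a group LV's loadings to its |BSR| > threshold elements."""
    mask = group_lv.stable_mask(bsr_threshold)
    if int(mask.sum()) < min_elements:
        raise ValueError(
            f"only {int(mask.sum())} stable elements (|BSR| > {bsr_threshold}); "
            f"need >= {min_elements}"
        )
    label = group_lv.contrast.label if group_lv.contrast is not None else "svd"
    return GroupPattern(group_lv.loadings[mask].copy(), mask, label, group,
                        bsr_threshold, cols)


def categorize(r: float | None) -> str:
    """Total, deterministic partition of [-1, 1] plus {absent}.

    r >= .4 -> moderate_strong (inclusive boundary); .1 < r < .4 -> weak
    positive; -.1 <= r <= .1 -> negligible; r < -.1 -> negative; absent ->
    negligible_or_none.
    """
    if r is None:
        return "negligible_or_none"
    if r >= 0.4:
        return "moderate_strong"
    if r > 0.1:
        return "weak_positive"
    if r >= -0.1:
        return "negligible_or_none"
    return "negative"


def assess_individual(individual_lv: LatentVariable, pattern: GroupPattern,
                      alpha: float = 0.05) -> SimilarityRecord:
    """Correlate an individual's loadings with the group pattern.

    The individual LV is sign-aligned so its design saliences have a
    positive dot product with the group contrast (a no-op for non-rotated
    LVs, whose saliences are the contrast itself).  If the individual
    analysis is non-significant or the contrast is not matched, no
    correlation is computed and the record falls in the negligible/none
    category.
    """
    if len(individual_lv.loadings) != len(pattern.mask):
        raise ValueError("feature grid mismatch between individual and pattern")
    p = float(individual_lv.p) if individual_lv.p is not None else 1.0

    loadings = individual_lv.loadings
    matched = True
    if individual_lv.contrast is not None:
        align = float(np.dot(individual_lv.saliences, individual_lv.contrast.unit))
        if align < 0:
            loadings = -loadings
        matched = True  # saliences are the contrast by construction
    if p >= alpha or not matched:
        return SimilarityRecord("", pattern.group, p, False, None,
                                "negligible_or_none")
    a = loadings[pattern.mask]
    b = pattern.loadings
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in loadings over the stable mask")
    r = float(np.corrcoef(a, b)[0, 1])
    return SimilarityRecord("", pattern.group, p, True, r, categorize(r))


@dataclass(frozen=True)
class RuleWindow:
    """One rating-rule window: a column selector plus the required loading
    sign (+1 = loading positive in the window, -1 = negative).

    ``timing`` optionally constrains the LV's brain-score condition profile
    (ordered by session): ``("early_change", q)`` requires the first-to-
    second session change to exceed q x the second-to-third change in
    magnitude, ``("no_early_change", q)`` requires it to stay below q x.
    """

    name: str
    selector: dict  # column-metadata constraints, e.g. {"frequency": (8, 14)}
    sign: int
    timing: tuple[str, float] | None = None

    def column_mask(self, cols: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(cols), dtype=bool)
        for key, bounds in self.selector.items():
            col = cols[key].to_numpy()
            mask &= (col >= bounds[0]) & (col <= bounds[1])
        if not mask.any():
            raise ValueError(f"empty rule window {self.name!r}")
        return mask


@dataclass(frozen=True)
class RatingRules:
    """Windows whose satisfaction (any one suffices) flags a pattern fit."""

    responder_windows: Sequence[RuleWindow]
    nonresponder_windows: Sequence[RuleWindow]
    bsr_threshold: float = 2.0
    # fraction of a window's elements that must be stable with the required
    # sign; 5% sits well above the ~2.5% per-sign chance rate at |BSR| > 2
    min_stable_fraction: float = 0.05


def _timing_ok(lv: LatentVariable, timing: tuple[str, float] | None) -> bool:
    if timing is None:
        return True
    means = [lv.condition_means[c] for c in lv.cell_labels]
    if len(means) != 3:
        raise ValueError("timing constraints need exactly 3 conditions")
    early = abs(means[0] - means[1])
    late = abs(means[1] - means[2])
    mode, q = timing
    if mode == "early_change":
        return early > q * late
    if mode == "no_early_change":
        return early < q * late
    raise ValueError(f"unknown timing mode {mode!r}")


def _window_hit(lv: LatentVariable, window: RuleWindow, cols: pd.DataFrame,
                bsr_threshold: float, min_fraction: float) -> bool:
    cmask = window.column_mask(cols)
    stable = lv.stable_mask(bsr_threshold) & cmask
    signed = stable & (np.sign(lv.loadings) == window.sign)
    opposite = stable & (np.sign(lv.loadings) == -window.sign)
    # a "meaningful" change needs both enough stable elements and a clear
    # predominant direction within the window
    if signed.sum() < max(1, min_fraction * cmask.sum()):
        return False
    if signed.sum() <= opposite.sum():
        return False
    return _timing_ok(lv, window.timing)


def rule_based_rating(lvs_by_contrast: dict[str, LatentVariable],
                      cols: pd.DataFrame, rules: RatingRules,
                      alpha: float = 0.05) -> tuple[bool, bool]:
    """Deterministic fits-responder / fits-non-responder flags.

    ``lvs_by_contrast`` maps a window's LV key (the contrast label named in
    ``window.selector.get('lv', ...)``; by default all windows read the sole
    LV provided) to the individual's non-rotated LV for that contrast.
    Windows only count when their LV is significant at ``alpha``.
    """
    def fits(windows: Sequence[RuleWindow]) -> bool:
        hit = False
        for w in windows:
            key = w.selector.get("lv", next(iter(lvs_by_contrast)))
            sel = {k: v for k, v in w.selector.items() if k != "lv"}
            lv = lvs_by_contrast[key]
            if lv.p is not None and lv.p >= alpha:
                continue
            ww = RuleWindow(w.name, sel, w.sign, w.timing)
            if _window_hit(lv, ww, cols, rules.bsr_threshold,
                           rules.min_stable_fraction):
                hit = True
        return hit

    return fits(rules.responder_windows), fits(rules.nonresponder_windows)


def rating_category(record: SimilarityRecord) -> str:
    """Four-way rating category from the rule flags and the own group."""
    own_fit = (record.fits_responder_rule if record.group == "responder"
               else record.fits_nonresponder_rule)
    opp_fit = (record.fits_nonresponder_rule if record.group == "responder"
               else record.fits_responder_rule)
    if own_fit and opp_fit:
        return "both"
    if own_fit:
        return "own_only"
    if opp_fit:
        return "opposite_only"
    return "neither"


def summarize_cohort(records: Sequence[SimilarityRecord]) -> dict:
    """Percentage per correlation category and per rating category, per
    group and overall.  Percentages within a scheme sum to 100."""
    if not records:
        raise ValueError("no records")

    def pct(recs: Sequence[SimilarityRecord]) -> dict:
        n = len(recs)
        out = {"n": n, "correlation": {}, "rating": {}}
        for cat in CATEGORIES:
            out["correlation"][cat] = round(
                100.0 * sum(r.category == cat for r in recs) / n, 4)
        rated = [r for r in recs if r.fits_responder_rule is not None]
        if rated:
            out["rating_n"] = len(rated)
            for cat in RATING_CATEGORIES:
                out["rating"][cat] = round(
                    100.0 * sum(rating_category(r) == cat for r in rated)
                    / len(rated), 4)
        return out

    groups = sorted({r.group for r in records})
    summary = {"overall": pct(records)}
    for g in groups:
        summary[g] = pct([r for r in records if r.group == g])
    return summary
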