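"""Mean-centered task PLS-SVD and non-rotated (contrast) PLS.

Mean-centered PLS averages the feature matrix within each group x condition
cell, removes the per-feature grand mean of the cell means, and decomposes
the centered cell-mean matrix by SVD.  Each latent variable (LV) couples a
singular value (effect strength), design saliences (the group/condition
contrast the LV expresses) and element loadings (the singular image over
features).  Inference follows the standard two-level scheme:

* **Permutation** — condition labels are shuffled within every participant
  and participants are reassigned to groups (group sizes preserved); the
  full centering + SVD is re-run and an LV's p-value is the add-one
  proportion of permuted singular values at least as large as the observed.
* **Bootstrap** — participants are resampled with replacement within group;
  each replicate's decomposition is aligned to the original by orthogonal
  Procrustes on the design saliences (resolving sign/order indeterminacy),
  and the bootstrap ratio (BSR) divides each element loading by its
  bootstrap standard error.  |BSR| >= 3.1 corresponds to roughly a 99%
  confidence interval and |BSR| > 2 to roughly 95%.

Brain scores (row feature vector . element loadings) summarize how strongly
every observation expresses an LV; bootstrap percentiles of the condition
means of replicate brain scores give 95% CIs on the condition profile.

Non-rotated PLS fixes the design salience a priori as a zero-sum contrast
(e.g. 0 1 -1 across sessions): the "loading" is the contrast-weighted sum of
centered condition means, its norm is the singular value, and inference
shuffles/resamples individual observations (epochs), which is the form used
for single-participant analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import svd

from .features import FeatureMatrix

__all__ = [
    "Contrast",
    "LatentVariable",
    "CenteredCells",
    "mean_center_cells",
    "pls_decompose",
    "brain_scores",
    "permutation_pvalues",
    "bootstrap_stability",
    "nonrotated_pls",
    "group_pls",
]

_BSR_CAP = 1e6


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass(frozen=True)
class Contrast:
    """Zero-sum condition weight vector (e.g. (0, 1, -1))."""

    weights: tuple
    label: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or np.allclose(w, 0):
            raise ValueError("contrast must be a nonzero vector")
        if abs(w.sum()) > 1e-9:
            raise ValueError("contrast weights must sum to 0")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @property
    def raw(self) -> np.ndarray:
        return np.asarray(self.weights)

    @property
    def unit(self) -> np.ndarray:
        w = self.raw
        return w / np.linalg.norm(w)


@dataclass
class LatentVariable:
    """One latent variable with its inferential annotations."""

    index: int
    singular_value: float
    saliences: np.ndarray  # design weights, one per cell
    loadings: np.ndarray  # singular image, one per feature
    cell_labels: list
    pcce: float | None  # % of summed squared singular values
    kind: str = "svd"  # "svd" | "nonrotated"
    contrast: Contrast | None = None
    p: float | None = None
    bsr: np.ndarray | None = None
    scores: np.ndarray | None = None  # brain score per observation row
    condition_means: dict | None = None  # cell -> mean brain score
    condition_ci: dict | None = None  # cell -> (lo, hi)
    boot_salience_corr: float | None = None  # mean corr of aligned replicate u

    def stable_mask(self, threshold: float = 2.0) -> np.ndarray:
        if self.bsr is None:
            raise ValueError("LV has no bootstrap ratios")
        return np.abs(self.bsr) > threshold

    def align_to_contrast(self, contrast: "Contrast") -> "LatentVariable":
        """Flip the LV's sign so its saliences have a positive dot product
        with the given condition contrast.

        An SVD latent variable's sign is arbitrary; fixing it against the
        predefined contrast makes its singular image directly comparable to
        non-rotated individual results using that contrast.
        """
        if len(self.saliences) % len(contrast.raw) != 0:
            raise ValueError("contrast length incompatible with saliences")
        reps = len(self.saliences) // len(contrast.raw)
        if float(self.saliences @ np.tile(contrast.unit, reps)) < 0:
            self.saliences = -self.saliences
            self.loadings = -self.loadings
            if self.bsr is not None:
                self.bsr = -self.bsr
            if self.scores is not None:
                self.scores = -self.scores
            if self.condition_means is not None:
                self.condition_means = {k: -v for k, v in self.condition_means.items()}
            if self.condition_ci is not None:
                self.condition_ci = {k: (-hi, -lo)
                                     for k, (lo, hi) in self.condition_ci.items()}
        return self


@dataclass
class CenteredCells:
    """Cell-mean matrix after grand-mean centering, plus the record of what
    was subtracted."""

    matrix: np.ndarray  # (n_cells, n_features)
    cell_labels: list  # [(group, condition), ...]
    grand_mean: np.ndarray  # (n_features,)
    cell_means: np.ndarray  # uncentered cell means


def _cells(rows: pd.DataFrame) -> tuple[list, list]:
    groups = list(pd.unique(rows["group"]))
    conds = list(pd.unique(rows["session"]))
    return groups, conds


def _cell_means(values: np.ndarray, groups_col, conds_col,
                groups: list, conds: list) -> np.ndarray:
    means = np.empty((len(groups) * len(conds), values.shape[1]))
    k = 0
    for g in groups:
        for c in conds:
            sel = (groups_col == g) & (conds_col == c)
            if not np.any(sel):
                raise ValueError(f"empty cell ({g!r}, {c!r})")
            means[k] = values[sel].mean(axis=0)
            k += 1
    return means


def mean_center_cells(fm: FeatureMatrix) -> CenteredCells:
    """Average within each group x condition cell, then subtract each
    feature's unweighted grand mean of the cell means."""
    groups, conds = _cells(fm.rows)
    g_col = fm.rows["group"].to_numpy()
    c_col = fm.rows["session"].to_numpy()
    means = _cell_means(fm.values, g_col, c_col, groups, conds)
    grand = means.mean(axis=0)
    labels = [(g, c) for g in groups for c in conds]
    return CenteredCells(means - grand, labels, grand, means)


def pls_decompose(centered: CenteredCells) -> list[LatentVariable]:
    """SVD of the centered cell-mean matrix; LVs ordered by decreasing
    singular value, saliences sign-fixed so each LV's largest-magnitude
    design weight is positive.  PCCE_i = 100 s_i^2 / sum_j s_j^2."""
    M = centered.matrix
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite centered matrix")
    U, s, Vt = svd(M, full_matrices=False)
    total = float(np.sum(s ** 2))
    lvs = []
    for i in range(len(s)):
        u, v = U[:, i].copy(), Vt[i].copy()
        if u[np.argmax(np.abs(u))] < 0:
            u, v = -u, -v
        pcce = 100.0 * s[i] ** 2 / total if total > 0 else 0.0
        lvs.append(LatentVariable(i, float(s[i]), u, v,
                                  list(centered.cell_labels), pcce))
    return lvs


def brain_scores(lv: LatentVariable, fm: FeatureMatrix) -> LatentVariable:
    """Attach per-row brain scores (row . loadings) and their cell means."""
    if fm.values.shape[1] != len(lv.loadings):
        raise ValueError("feature count does not match loading length")
    scores = fm.values @ lv.loadings
    lv.scores = scores
    g_col = fm.rows["group"].to_numpy()
    c_col = fm.rows["session"].to_numpy()
    lv.condition_means = {
        cell: float(scores[(g_col == cell[0]) & (c_col == cell[1])].mean())
        for cell in lv.cell_labels
    }
    return lv


def _participant_rows(rows: pd.DataFrame) -> tuple[list, dict, dict]:
    pids = list(pd.unique(rows["participant"]))
    idx = {p: np.flatnonzero((rows["participant"] == p).to_numpy()) for p in pids}
    grp = {p: rows.loc[idx[p][0], "group"] for p in pids}
    return pids, idx, grp


def permutation_pvalues(fm: FeatureMatrix, n_perm: int = 500,
                        seed=0) -> np.ndarray:
    """Permutation p-values per LV: each permutation shuffles condition
    labels within every participant and reassigns participants to groups
    (sizes preserved), then re-runs centering + SVD.  Add-one estimator:
    p_i = (1 + #{s_perm_i >= s_obs_i}) / (n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    groups, conds = _cells(fm.rows)
    g_col = fm.rows["group"].to_numpy().copy()
    c_col = fm.rows["session"].to_numpy().copy()
    s_obs = svd(mean_center_cells(fm).matrix, compute_uv=False)

    pids, idx, grp = _participant_rows(fm.rows)
    group_list = np.array([grp[p] for p in pids])
    exceed = np.zeros(len(s_obs))
    for _ in range(n_perm):
        g_perm = np.empty_like(g_col)
        c_perm = np.empty_like(c_col)
        shuffled_groups = group_list[rng.permutation(len(pids))]
        for p, g_new in zip(pids, shuffled_groups):
            rows_p = idx[p]
            g_perm[rows_p] = g_new
            c_perm[rows_p] = c_col[rows_p][rng.permutation(len(rows_p))]
        means = _cell_means(fm.values, g_perm, c_perm, groups, conds)
        s_perm = svd(means - means.mean(axis=0), compute_uv=False)
        exceed += s_perm >= s_obs
    return (1.0 + exceed) / (n_perm + 1.0)


def bootstrap_stability(fm: FeatureMatrix, lvs: Sequence[LatentVariable],
                        n_boot: int = 200, seed=0,
                        ci: tuple[float, float] = (2.5, 97.5)) -> list[LatentVariable]:
    """Bootstrap ratios and brain-score condition-mean CIs.

    Participants are resampled with replacement within group (original group
    sizes); each replicate is re-centered and re-decomposed, aligned to the
    original decomposition by orthogonal Procrustes on the design saliences,
    and BSR_e = loading_e / SE_boot(loading_e).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    groups, conds = _cells(fm.rows)
    pids, idx, grp = _participant_rows(fm.rows)
    by_group = {g: [p for p in pids if grp[p] == g] for g in groups}
    for g, members in by_group.items():
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 participants")
    U_o = np.column_stack([lv.saliences for lv in lvs])
    k = U_o.shape[1]

    v_stack = np.empty((n_boot, fm.values.shape[1], k))
    cm_stack = np.empty((n_boot, len(lvs[0].cell_labels), k))
    u_corr = np.zeros(k)  # alignment diagnostic: corr(replicate u, original u)
    for b in range(n_boot):
        for attempt in range(10):
            row_idx, g_lab, c_lab = [], [], []
            for g in groups:
                members = by_group[g]
                draw = rng.integers(0, len(members), size=len(members))
                for d in draw:
                    p = members[d]
                    row_idx.extend(idx[p])
                    g_lab.extend([g] * len(idx[p]))
                    c_lab.extend(fm.rows["session"].to_numpy()[idx[p]])
            try:
                vals = fm.values[np.asarray(row_idx)]
                means = _cell_means(vals, np.asarray(g_lab), np.asarray(c_lab),
                                    groups, conds)
                break
            except ValueError:
                if attempt == 9:
                    raise
        Ub, sb, Vbt = svd(means - means.mean(axis=0), full_matrices=False)
        A, _, Bt = svd(Ub[:, :k].T @ U_o, full_matrices=False)
        R = A @ Bt
        Vb_rot = Vbt[:k].T @ R
        Ub_rot = Ub[:, :k] @ R
        for j in range(k):
            if Ub_rot[:, j].std() > 0 and U_o[:, j].std() > 0:
                cu = np.corrcoef(Ub_rot[:, j], U_o[:, j])[0, 1]
                u_corr[j] += cu / n_boot
        v_stack[b] = Vb_rot
        scores_b = vals @ Vb_rot
        cm_stack[b] = _cell_means(scores_b, np.asarray(g_lab),
                                  np.asarray(c_lab), groups, conds)

    se = v_stack.std(axis=0, ddof=1)
    lo, hi = np.percentile(cm_stack, ci, axis=0)
    for j, lv in enumerate(lvs):
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr = lv.loadings / se[:, j]
        bsr = np.where(se[:, j] > 0, bsr, 0.0)
        lv.bsr = np.clip(bsr, -_BSR_CAP, _BSR_CAP)
        lv.condition_ci = {cell: (float(lo[c, j]), float(hi[c, j]))
                           for c, cell in enumerate(lv.cell_labels)}
        lv.boot_salience_corr = float(u_corr[j])
    return list(lvs)


def group_pls(fm: FeatureMatrix, n_perm: int = 500, n_boot: int = 200,
              seed=0) -> list[LatentVariable]:
    """Full mean-centered PLS-SVD: decomposition, permutation p-values,
    bootstrap ratios / CIs and brain scores for every LV."""
    s_perm, s_boot = _seedseq(seed).spawn(2)
    centered = mean_center_cells(fm)
    lvs = pls_decompose(centered)
    pvals = permutation_pvalues(fm, n_perm=n_perm, seed=s_perm)
    for lv, p in zip(lvs, pvals):
        lv.p = float(p)
        brain_scores(lv, fm)
    bootstrap_stability(fm, lvs, n_boot=n_boot, seed=s_boot)
    return lvs


def nonrotated_pls(fm: FeatureMatrix, contrast: Contrast,
                   n_perm: int = 500, n_boot: int = 200, seed=0,
                   ci: tuple[float, float] = (2.5, 97.5)) -> LatentVariable:
    """Hypothesis-driven PLS against a predefined condition contrast.

    Condition means are grand-mean centered per feature; the loading vector
    is the contrast-weighted sum of centered means (unit-norm contrast), the
    singular value is its Euclidean norm.  The permutation p shuffles
    condition labels across observations (epochs exchangeable under the
    null); the bootstrap resamples observations within condition.
    """
    conds = list(pd.unique(fm.rows["session"]))
    c = contrast.unit
    if len(c) != len(conds):
        raise ValueError("contrast length does not match number of conditions")
    c_col = fm.rows["session"].to_numpy()
    for cond in conds:
        if np.sum(c_col == cond) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 observations")

    def raw_loadings(values, labels):
        means = np.stack([values[labels == cond].mean(axis=0) for cond in conds])
        centered = means - means.mean(axis=0)
        return c @ centered

    raw = raw_loadings(fm.values, c_col)
    s = float(np.linalg.norm(raw))
    v = raw / s if s > 0 else np.zeros_like(raw)

    rng_p, rng_b = (np.random.default_rng(x) for x in _seedseq(seed).spawn(2))
    exceed = 0
    for _ in range(n_perm):
        s_perm = np.linalg.norm(raw_loadings(fm.values, rng_p.permutation(c_col)))
        exceed += s_perm >= s
    p = (1.0 + exceed) / (n_perm + 1.0)

    cond_idx = {cond: np.flatnonzero(c_col == cond) for cond in conds}
    raw_stack = np.empty((n_boot, len(raw)))
    cm_stack = np.empty((n_boot, len(conds)))
    for b in range(n_boot):
        rows_b, labs_b = [], []
        for cond in conds:
            ix = cond_idx[cond]
            rows_b.append(ix[rng_b.integers(0, len(ix), size=len(ix))])
            labs_b.extend([cond] * len(ix))
        rows_b = np.concatenate(rows_b)
        labs_b = np.asarray(labs_b)
        raw_b = raw_loadings(fm.values[rows_b], labs_b)
        raw_stack[b] = raw_b
        nb = np.linalg.norm(raw_b)
        v_b = raw_b / nb if nb > 0 else np.zeros_like(raw_b)
        scores_b = fm.values[rows_b] @ v_b
        cm_stack[b] = [scores_b[labs_b == cond].mean() for cond in conds]

    se = raw_stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = raw / se
    bsr = np.clip(np.where(se > 0, bsr, 0.0), -_BSR_CAP, _BSR_CAP)
    lo, hi = np.percentile(cm_stack, ci, axis=0)

    lv = LatentVariable(0, s, c.copy(), v, list(conds), None,
                        kind="nonrotated", contrast=contrast, p=float(p),
                        bsr=bsr)
    lv.scores = fm.values @ v
    lv.condition_means = {cond: float(lv.scores[c_col == cond].mean())
                          for cond in conds}
    lv.condition_ci = {cond: (float(lo[i]), float(hi[i]))
                       for i, cond in enumerate(conds)}
    return lv
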