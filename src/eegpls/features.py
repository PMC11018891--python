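"""Assembly of PLS-ready feature matrices and age-confound regression.

Group-level matrices stack one row per participant x session (group-major,
then participant, then session), with columns the flattened element grid:
frequency x channel-pair for WPLI (frequency-major) or channel x timescale
for MSE (channel-major).  Single-participant matrices stack one row per
epoch, grouped by session, over the same column grid.

Because the two outcome groups differ in age and both connectivity and
complexity change with age, age is regressed out of every column (one
pooled ordinary-least-squares fit per column across all rows) before the
group-level statistics; residuals keep the column's grand mean so features
stay on their original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "wpli_column_metadata",
    "mse_column_metadata",
    "assemble_group_matrix",
    "assemble_individual_matrix",
    "regress_out_age",
]


@dataclass
class FeatureMatrix:
    """Observations x features with row/column metadata."""

    values: np.ndarray  # (n_rows, n_cols)
    rows: pd.DataFrame  # group, participant, session [, epoch, age]
    cols: pd.DataFrame  # kind + element identity
    provenance: str  # "group-level" | "single-participant"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError("values shape does not match metadata")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def wpli_column_metadata(grid, pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Column metadata for a flattened frequency x pair grid (frequency-major)."""
    freqs = np.repeat(grid.freqs, len(pairs))
    a = [p[0] for p in pairs] * len(grid.freqs)
    b = [p[1] for p in pairs] * len(grid.freqs)
    return pd.DataFrame({"kind": "wpli", "frequency": freqs,
                         "channel_a": a, "channel_b": b})


def mse_column_metadata(channel_labels: Sequence[str], scales: np.ndarray) -> pd.DataFrame:
    """Column metadata for a flattened channel x scale grid (channel-major)."""
    ch = np.repeat(list(channel_labels), len(scales))
    sc = np.tile(np.asarray(scales), len(channel_labels))
    return pd.DataFrame({"kind": "mse", "channel": ch, "scale": sc})


def _flatten(matrix_values: np.ndarray) -> np.ndarray:
    # row-major flatten matches the column metadata builders above
    return np.asarray(matrix_values, dtype=float).ravel()


def assemble_group_matrix(
    feature_maps: Mapping[tuple[str, str], np.ndarray],
    participants: Sequence[tuple[str, str]],  # (pid, group), group-major order
    sessions: Sequence[str],
    cols: pd.DataFrame,
    ages: Mapping[str, float] | None = None,
) -> FeatureMatrix:
    """Stack per-(participant, session) element grids into a group matrix.

    ``feature_maps[(pid, session)]`` is the 2-D element grid (frequency x
    pair, or channel x scale).  Every participant must have every session.
    """
    rows = []
    blocks = []
    shape0 = None
    for pid, group in participants:
        for session in sessions:
            if (pid, session) not in feature_maps:
                raise ValueError(f"missing session {session!r} for {pid!r}")
            v = np.asarray(feature_maps[(pid, session)])
            if shape0 is None:
                shape0 = v.shape
            elif v.shape != shape0:
                raise ValueError("inconsistent feature grids across participants")
            blocks.append(_flatten(v))
            rows.append({"group": group, "participant": pid, "session": session,
                         "age": None if ages is None else ages[pid]})
    values = np.vstack(blocks)
    fm = FeatureMatrix(values, pd.DataFrame(rows), cols.reset_index(drop=True),
                       "group-level")
    fm.validate()
    return fm


def assemble_individual_matrix(
    per_epoch_maps: Mapping[str, Sequence[np.ndarray]],
    sessions: Sequence[str],
    cols: pd.DataFrame,
    participant_id: str,
    group: str | None = None,
) -> FeatureMatrix:
    """Stack one participant's per-epoch element grids, rows grouped by
    session (sessions are the PLS conditions)."""
    rows = []
    blocks = []
    for session in sessions:
        maps = per_epoch_maps.get(session, [])
        if len(maps) < 2:
            raise ValueError(f"session {session!r} has fewer than 2 epochs")
        for ep, v in enumerate(maps):
            blocks.append(_flatten(np.asarray(v)))
            rows.append({"group": group, "participant": participant_id,
                         "session": session, "epoch": ep})
    fm = FeatureMatrix(np.vstack(blocks), pd.DataFrame(rows),
                       cols.reset_index(drop=True), "single-participant")
    fm.validate()
    return fm


def regress_out_age(fm: FeatureMatrix, ages: Mapping[str, float] | None = None) -> FeatureMatrix:
    """Remove the linear age trend from every column (pooled OLS), keeping
    each column's grand mean.

    Slopes and intercepts are retained in ``extra['age_slope']`` /
    ``extra['age_intercept']``.
    """
    if fm.provenance != "group-level":
        raise ValueError("age regression applies to group-level matrices")
    if ages is None:
        age = fm.rows["age"].to_numpy(dtype=float)
    else:
        age = fm.rows["participant"].map(ages).to_numpy(dtype=float)
    if not np.all(np.isfinite(age)):
        raise ValueError("missing ages")
    if np.ptp(age) == 0:
        raise ValueError("constant age vector; slope undefined")
    X = np.column_stack([np.ones_like(age), age])
    beta, *_ = np.linalg.lstsq(X, fm.values, rcond=None)
    resid = fm.values - X @ beta
    out = FeatureMatrix(resid + fm.values.mean(axis=0, keepdims=True),
                        fm.rows.copy(), fm.cols.copy(), fm.provenance,
                        dict(fm.extra))
    out.extra["age_intercept"] = beta[0]
    out.extra["age_slope"] = beta[1]
    return out
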