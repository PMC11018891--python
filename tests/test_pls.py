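"""PLS-SVD engine: decomposition oracles, inference behaviour, invariants."""

import numpy as np
import pandas as pd
import pytest

import eegpls as e
from eegpls.pls import mean_center_cells, pls_decompose, CenteredCells


def make_fm(values, groups, sessions, participants, epochs=None):
    rows = pd.DataFrame({"group": groups, "participant": participants,
                         "session": sessions})
    if epochs is not None:
        rows["epoch"] = epochs
    cols = pd.DataFrame({"kind": "x", "idx": np.arange(values.shape[1])})
    prov = "group-level" if epochs is None else "single-participant"
    return e.FeatureMatrix(np.asarray(values, dtype=float), rows, cols, prov)


def structured_fm(rng, n_r=8, n_n=6, n_feat=40, effect=2.0, n_inj=6):
    """Group-level matrix with a group x session interaction injected on the
    first ``n_inj`` features."""
    participants, groups, sessions, vals = [], [], [], []
    profile = {("responder", "baseline"): effect, ("responder", "week1"): effect,
               ("nonresponder", "week12"): effect}
    for g, n in (("responder", n_r), ("nonresponder", n_n)):
        for i in range(n):
            pid = f"{g[0]}{i}"
            for s in e.SESSIONS:
                row = rng.normal(size=n_feat)
                row[:n_inj] += profile.get((g, s), 0.0)
                participants.append(pid)
                groups.append(g)
                sessions.append(s)
                vals.append(row)
    return make_fm(np.array(vals), groups, sessions, participants)


class TestMeanCentering:
    def test_identical_cells_center_to_zero(self):
        v = np.tile([1.0, 2.0, 3.0], (12, 1))
        fm = make_fm(v, ["responder"] * 6 + ["nonresponder"] * 6,
                     list(e.SESSIONS) * 4, [f"p{i//3}" for i in range(12)])
        cc = mean_center_cells(fm)
        np.testing.assert_allclose(cc.matrix, 0.0, atol=1e-12)

    def test_hand_computed_cells(self):
        """2 groups x 2 conditions with cell means {0,0,1,1} on one feature
        center to {-.5,-.5,.5,.5}."""
        rows = pd.DataFrame({
            "group": ["g1", "g1", "g2", "g2"],
            "participant": ["a", "a", "b", "b"],
            "session": ["s1", "s2", "s1", "s2"],
        })
        fm = e.FeatureMatrix(np.array([[0.0], [0.0], [1.0], [1.0]]), rows,
                             pd.DataFrame({"kind": ["x"]}), "group-level")
        cc = mean_center_cells(fm)
        np.testing.assert_allclose(cc.matrix[:, 0], [-0.5, -0.5, 0.5, 0.5])

    def test_centered_columns_sum_to_zero(self, rng):
        cc = mean_center_cells(structured_fm(rng))
        np.testing.assert_allclose(cc.matrix.mean(axis=0), 0.0, atol=1e-12)


class TestDecomposition:
    def test_rank_one_matrix(self, rng):
        u0 = np.array([0.5, 0.5, -0.5, -0.5])
        v0 = rng.normal(size=9)
        v0 /= np.linalg.norm(v0)
        cc = CenteredCells(3.7 * np.outer(u0, v0), [("g", c) for c in "abcd"],
                           np.zeros(9), None)
        lvs = pls_decompose(cc)
        assert lvs[0].singular_value == pytest.approx(3.7, abs=1e-10)
        assert lvs[0].pcce == pytest.approx(100.0, abs=1e-9)
        np.testing.assert_allclose(np.abs(lvs[0].saliences), np.abs(u0),
                                   atol=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        """3x3 SVD agrees (up to sign) with an independent eigen-route:
        right vectors from eig(M^T M), singular values from its spectrum."""
        for _ in range(10):
            M = rng.normal(size=(3, 3))
            cc = CenteredCells(M, [("g", c) for c in "abc"], np.zeros(3), None)
            lvs = pls_decompose(cc)
            w, V = np.linalg.eigh(M.T @ M)
            order = np.argsort(w)[::-1]
            s_oracle = np.sqrt(np.maximum(w[order], 0.0))
            for i, lv in enumerate(lvs):
                assert lv.singular_value == pytest.approx(s_oracle[i], abs=1e-10)
                dot = abs(lv.loadings @ V[:, order[i]])
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_pcce_sums_to_100(self, rng):
        lvs = pls_decompose(mean_center_cells(structured_fm(rng)))
        assert sum(lv.pcce for lv in lvs) == pytest.approx(100.0, abs=1e-9)

    def test_reconstruction_and_orthogonality(self, rng):
        cc = mean_center_cells(structured_fm(rng))
        lvs = pls_decompose(cc)
        recon = sum(lv.singular_value * np.outer(lv.saliences, lv.loadings)
                    for lv in lvs)
        np.testing.assert_allclose(recon, cc.matrix, atol=1e-10)
        U = np.column_stack([lv.saliences for lv in lvs])
        V = np.column_stack([lv.loadings for lv in lvs])
        np.testing.assert_allclose(U.T @ U, np.eye(len(lvs)), atol=1e-10)
        np.testing.assert_allclose(V.T @ V, np.eye(len(lvs)), atol=1e-10)


class TestBrainScores:
    def test_one_hot_loading_reads_column(self, rng):
        fm = structured_fm(rng, n_feat=5)
        cc = mean_center_cells(fm)
        lv = pls_decompose(cc)[0]
        lv.loadings = np.eye(5)[2]
        e.brain_scores(lv, fm)
        np.testing.assert_allclose(lv.scores, fm.values[:, 2])

    def test_hand_dot_products(self):
        rows = pd.DataFrame({"group": ["g", "g"], "participant": ["a", "b"],
                             "session": ["s1", "s1"]})
        fm = e.FeatureMatrix(np.array([[1.0, 2.0], [0.0, 0.0]]), rows,
                             pd.DataFrame({"kind": ["x", "x"]}), "group-level")
        lv = e.LatentVariable(0, 1.0, np.array([1.0]), np.array([3.0, -1.0]),
                              [("g", "s1")], 100.0)
        e.brain_scores(lv, fm)
        assert lv.scores[0] == pytest.approx(1.0)  # 1*3 + 2*(-1)
        assert lv.scores[1] == 0.0


class TestPermutation:
    def test_strong_effect_reaches_minimum_p(self, rng):
        fm = structured_fm(rng, effect=6.0)
        p = e.permutation_pvalues(fm, n_perm=99, seed=3)
        assert p[0] == pytest.approx(1.0 / 100.0)

    def test_deterministic_given_seed(self, rng):
        fm = structured_fm(rng)
        p1 = e.permutation_pvalues(fm, n_perm=50, seed=11)
        p2 = e.permutation_pvalues(fm, n_perm=50, seed=11)
        np.testing.assert_array_equal(p1, p2)

    def test_pvalues_never_zero(self, rng):
        fm = structured_fm(rng, effect=0.0)
        p = e.permutation_pvalues(fm, n_perm=20, seed=1)
        assert np.all(p > 0) and np.all(p <= 1)


class TestBootstrap:
    def test_deterministic_given_seed(self, rng):
        fm = structured_fm(rng)
        lvs1 = e.group_pls(fm, n_perm=10, n_boot=25, seed=2)
        lvs2 = e.group_pls(fm, n_perm=10, n_boot=25, seed=2)
        np.testing.assert_array_equal(lvs1[0].bsr, lvs2[0].bsr)

    def test_injected_elements_are_stable(self, rng):
        """Strong injected elements reach |BSR| >= 3.1; few null elements
        do."""
        fm = structured_fm(rng, n_r=12, n_n=9, n_feat=60, effect=2.5, n_inj=8)
        lvs = e.group_pls(fm, n_perm=10, n_boot=100, seed=4)
        bsr = np.abs(lvs[0].bsr)
        assert (bsr[:8] >= 3.1).mean() >= 0.8
        assert (bsr[8:] >= 3.1).mean() < 0.05

    def test_duplicated_cohort_increases_bsr(self, rng):
        """Doubling every participant halves the bootstrap SE, inflating
        BSR magnitudes at the injected elements."""
        fm = structured_fm(rng, n_r=6, n_n=5, n_feat=30, effect=2.0, n_inj=5)
        dup_vals = np.vstack([fm.values, fm.values])
        dup_rows = pd.concat([fm.rows,
                              fm.rows.assign(participant=fm.rows["participant"] + "x")],
                             ignore_index=True)
        fm_dup = e.FeatureMatrix(dup_vals, dup_rows, fm.cols, fm.provenance)
        lv = e.group_pls(fm, n_perm=5, n_boot=80, seed=6)[0]
        lv_dup = e.group_pls(fm_dup, n_perm=5, n_boot=80, seed=6)[0]
        assert np.abs(lv_dup.bsr[:5]).mean() > np.abs(lv.bsr[:5]).mean()

    def test_procrustes_alignment_of_dominant_lv(self, rng):
        """With a dominant LV (PCCE > 70), aligned bootstrap saliences
        correlate > 0.9 with the original."""
        fm = structured_fm(rng, n_r=10, n_n=8, n_feat=30, effect=4.0, n_inj=10)
        lvs = e.group_pls(fm, n_perm=5, n_boot=60, seed=8)
        assert lvs[0].pcce > 70
        assert lvs[0].boot_salience_corr > 0.9


class TestScaleEquivariance:
    def test_scaling_matrix_scales_singular_values_only(self, rng):
        fm = structured_fm(rng)
        fm_k = e.FeatureMatrix(fm.values * 7.0, fm.rows, fm.cols, fm.provenance)
        lvs = e.group_pls(fm, n_perm=30, n_boot=30, seed=9)
        lvs_k = e.group_pls(fm_k, n_perm=30, n_boot=30, seed=9)
        assert lvs_k[0].singular_value == pytest.approx(
            7.0 * lvs[0].singular_value, rel=1e-10)
        assert lvs_k[0].p == lvs[0].p
        np.testing.assert_allclose(lvs_k[0].loadings, lvs[0].loadings, atol=1e-10)
        np.testing.assert_allclose(lvs_k[0].bsr, lvs[0].bsr, rtol=1e-8)


class TestNonRotated:
    def _epoch_fm(self, rng, shift=(0.0, 1.0, 0.0), n_ep=20, n_feat=12, n_inj=4):
        vals, sessions, epochs = [], [], []
        for s, d in zip(e.SESSIONS, shift):
            for ep in range(n_ep):
                row = rng.normal(size=n_feat)
                row[:n_inj] += d
                vals.append(row)
                sessions.append(s)
                epochs.append(ep)
        return make_fm(np.array(vals), ["g"] * len(vals), sessions,
                       ["p"] * len(vals), epochs=epochs)

    def test_two_condition_closed_form(self, rng):
        """Contrast (1,-1)/sqrt(2): loadings proportional to the condition
        mean difference, singular value = ||difference|| / sqrt(2)."""
        vals, sessions = [], []
        for s in ("s1", "s2"):
            for _ in range(15):
                vals.append(rng.normal(size=8) + (1.0 if s == "s1" else 0.0))
                sessions.append(s)
        fm = make_fm(np.array(vals), ["g"] * 30, sessions, ["p"] * 30,
                     epochs=list(range(15)) * 2)
        lv = e.nonrotated_pls(fm, e.Contrast((1, -1)), n_perm=30, n_boot=20,
                              seed=1)
        d = (fm.values[np.array(sessions) == "s1"].mean(0)
             - fm.values[np.array(sessions) == "s2"].mean(0))
        assert lv.singular_value == pytest.approx(np.linalg.norm(d) / np.sqrt(2),
                                                  abs=1e-10)
        np.testing.assert_allclose(lv.loadings, d / np.linalg.norm(d), atol=1e-10)

    def test_equal_condition_means_give_null(self):
        vals = np.tile(np.arange(6.0), (30, 1))
        fm = make_fm(vals, ["g"] * 30, list(e.SESSIONS) * 10, ["p"] * 30,
                     epochs=list(range(10)) * 3)
        lv = e.nonrotated_pls(fm, e.Contrast((0, 1, -1)), n_perm=49, n_boot=10,
                              seed=2)
        assert lv.singular_value == pytest.approx(0.0, abs=1e-12)
        assert lv.p > 0.9

    def test_injected_week1_to_week12_decrease(self, rng):
        """A week1 -> week12 drop with contrast (0,1,-1) is significant with
        positive loadings at the injected elements (positive weight sits on
        week 1, so week1 > week12 loads positively)."""
        fm = self._epoch_fm(rng, shift=(0.5, 1.0, 0.0))
        lv = e.nonrotated_pls(fm, e.Contrast((0, 1, -1)), n_perm=99,
                              n_boot=50, seed=3)
        assert lv.p < 0.05
        assert np.all(lv.loadings[:4] > 0)
        assert np.abs(lv.bsr[:4]).mean() > 2.0

    def test_deterministic_and_scale_equivariant(self, rng):
        fm = self._epoch_fm(rng)
        lv1 = e.nonrotated_pls(fm, e.Contrast((0, 1, -1)), n_perm=30,
                               n_boot=20, seed=4)
        fm_k = e.FeatureMatrix(fm.values * 3.0, fm.rows, fm.cols, fm.provenance)
        lv2 = e.nonrotated_pls(fm_k, e.Contrast((0, 1, -1)), n_perm=30,
                               n_boot=20, seed=4)
        assert lv2.p == lv1.p
        assert lv2.singular_value == pytest.approx(3.0 * lv1.singular_value)
        np.testing.assert_allclose(lv2.bsr, lv1.bsr, rtol=1e-8)

    def test_contrast_validation(self):
        with pytest.raises(ValueError):
            e.Contrast((1, 1, -1))  # does not sum to zero
        with pytest.raises(ValueError):
            e.Contrast((0, 0, 0))
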