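"""Permutation tests, edge-wise GLM, NBS, and chi-square counts."""

import numpy as np
import pytest
from scipy import stats

from memnet.group_stats import (
    ComponentResult,
    EdgeGroupResult,
    chi_square_counts,
    count_reduced,
    edgewise_glm_t,
    nbs,
    permutation_mean_test,
)


class TestPermutationMeanTest:
    def test_identical_groups_give_p_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        _, _, p = permutation_mean_test(v, v.copy(), n_perm=500, seed=0)
        assert p == 1.0

    def test_two_sidedness_label_swap(self, rng):
        a, b = rng.standard_normal(20), rng.standard_normal(20) + 0.7
        _, _, p_ab = permutation_mean_test(a, b, n_perm=2000, seed=5)
        _, _, p_ba = permutation_mean_test(b, a, n_perm=2000, seed=5)
        assert p_ab == p_ba

    def test_power_for_one_sd_shift(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.standard_normal(36) + 1.0
            b = rng.standard_normal(36)
            _, _, p = permutation_mean_test(a, b, n_perm=300, seed=int(rng.integers(2**31)))
            hits += p < 0.05
        assert hits >= 90

    def test_type_i_error_calibrated(self, rng):
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.standard_normal(15)
            b = rng.standard_normal(15)
            _, _, p = permutation_mean_test(a, b, n_perm=200, seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_mean_test([], [1.0], seed=0)


class TestEdgewiseGlm:
    def test_equals_pooled_two_sample_t(self, rng):
        y = rng.standard_normal((30, 40))
        is_ad = np.zeros(30)
        is_ad[:14] = 1
        t_glm = edgewise_glm_t(y, is_ad)
        t_ref = stats.ttest_ind(y[is_ad == 0], y[is_ad == 1], equal_var=True).statistic
        assert np.allclose(t_glm, t_ref, atol=1e-10)

    def test_sign_convention_controls_minus_ad(self, rng):
        y = rng.standard_normal((40, 5))
        is_ad = np.zeros(40)
        is_ad[:20] = 1
        y[is_ad == 0] += 2.0  # controls higher
        assert (edgewise_glm_t(y, is_ad) > 0).all()

    def test_constant_group_rejected(self, rng):
        with pytest.raises(ValueError, match="rank"):
            edgewise_glm_t(rng.standard_normal((20, 3)), np.ones(20))

    def test_orthogonal_covariates_leave_beta(self, rng):
        n = 40
        is_ad = np.zeros(n)
        is_ad[: n // 2] = 1
        # covariate orthogonal to intercept and group
        cov = rng.standard_normal(n)
        cov[: n // 2] -= cov[: n // 2].mean()
        cov[n // 2 :] -= cov[n // 2 :].mean()
        y = rng.standard_normal((n, 10))
        x0 = np.column_stack([np.ones(n), is_ad])
        x1 = np.column_stack([np.ones(n), is_ad, cov])
        b0 = np.linalg.lstsq(x0, y, rcond=None)[0][1]
        b1 = np.linalg.lstsq(x1, y, rcond=None)[0][1]
        assert np.allclose(b0, b1, atol=1e-10)
        # the t maps agree closely (df changes only the error estimate)
        t0 = edgewise_glm_t(y, is_ad)
        t1 = edgewise_glm_t(y, is_ad, covariates=cov)
        assert np.corrcoef(t0, t1)[0, 1] > 0.99

    def test_null_t_follows_student_t(self, rng):
        n = 72
        is_ad = np.zeros(n)
        is_ad[:36] = 1
        cov = rng.standard_normal((n, 2))
        t = edgewise_glm_t(rng.standard_normal((n, 3000)), is_ad, covariates=cov)
        ks = stats.kstest(t, "t", args=(n - 4,))
        assert ks.pvalue > 0.01


class TestNbs:
    @staticmethod
    def _null_stack(rng, n_sub=40, n_nodes=12):
        y = rng.standard_normal((n_sub, n_nodes * (n_nodes - 1) // 2))
        is_ad = np.zeros(n_sub)
        is_ad[: n_sub // 2] = 1
        return y, is_ad

    def test_infinite_threshold_empty(self, rng):
        y, is_ad = self._null_stack(rng)
        res = nbs(y, is_ad, threshold_t=np.inf, n_perm=100, seed=0)
        assert not res.supra_mask.any()
        assert res.components == []
        assert res.reduced_nodes == set()

    def test_planted_deficit_recovered(self, rng):
        # dense 8-node AD deficit inside a 20-node network
        n_nodes, n_sub = 20, 72
        iu = np.triu_indices(n_nodes, 1)
        planted = {
            k for k, (i, j) in enumerate(zip(*iu)) if i < 8 and j < 8
        }
        is_ad = np.zeros(n_sub)
        is_ad[:36] = 1
        y = 0.15 * rng.standard_normal((n_sub, len(iu[0])))
        for k in planted:
            y[is_ad == 1, k] -= 0.2
        res = nbs(y, is_ad, n_perm=400, seed=1)
        recovered = {
            k
            for k, (i, j) in enumerate(zip(*iu))
            if (i, j) in {tuple(e) for e in res.reduced_edges}
        }
        recall = len(recovered & planted) / len(planted)
        assert recall >= 0.8

    def test_reduced_set_shrinks_with_threshold(self, rng):
        n_nodes, n_sub = 16, 60
        iu = np.triu_indices(n_nodes, 1)
        is_ad = np.zeros(n_sub)
        is_ad[:30] = 1
        y = 0.2 * rng.standard_normal((n_sub, len(iu[0])))
        y[is_ad == 1, :40] -= 0.25
        res_lo = nbs(y, is_ad, threshold_t=2.5, n_perm=300, seed=2)
        res_hi = nbs(y, is_ad, threshold_t=4.5, n_perm=300, seed=2)
        assert res_hi.reduced_nodes <= res_lo.reduced_nodes

    def test_covariates_stay_with_subjects(self, rng):
        y, is_ad = self._null_stack(rng)
        cov = np.column_stack([rng.normal(70, 5, len(is_ad)), rng.integers(0, 2, len(is_ad))])
        res = nbs(y, is_ad, covariates=cov, n_perm=200, seed=3)
        assert res.threshold_t == pytest.approx(
            stats.t.ppf(1 - 0.005, len(is_ad) - 4)
        )


class TestCountReduced:
    @staticmethod
    def _result(components, n_nodes=6):
        iu = np.triu_indices(n_nodes, 1)
        n_edges = len(iu[0])
        return EdgeGroupResult(
            node_ids=list(range(n_nodes)),
            edge_index=np.column_stack(iu),
            t_map=np.zeros(n_edges),
            threshold_t=3.0,
            supra_mask=np.zeros(n_edges, dtype=bool),
            components=components,
            alpha=0.05,
            phase="retrieval",
        )

    def test_empty_mask(self):
        summary = count_reduced(self._result([]))
        assert (summary.n_reduced_nodes, summary.n_reduced_edges) == (0, 0)

    def test_single_edge(self):
        comp = ComponentResult(edges=[(0, 1)], nodes=[0, 1], sign=1, p=0.01)
        summary = count_reduced(self._result([comp]))
        assert (summary.n_reduced_nodes, summary.n_reduced_edges) == (2, 1)

    def test_triangle(self):
        comp = ComponentResult(
            edges=[(0, 1), (0, 2), (1, 2)], nodes=[0, 1, 2], sign=1, p=0.002
        )
        summary = count_reduced(self._result([comp]))
        assert (summary.n_reduced_nodes, summary.n_reduced_edges) == (3, 3)

    def test_nonsignificant_or_increased_ignored(self):
        comps = [
            ComponentResult(edges=[(0, 1)], nodes=[0, 1], sign=1, p=0.2),
            ComponentResult(edges=[(2, 3)], nodes=[2, 3], sign=-1, p=0.001),
        ]
        summary = count_reduced(self._result(comps))
        assert (summary.n_reduced_nodes, summary.n_reduced_edges) == (0, 0)


class TestChiSquare:
    def test_equal_proportions(self):
        chi2, p = chi_square_counts(5, 20, 5, 20)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            chi_square_counts(10, 5, 1, 5)
        with pytest.raises(ValueError, match="margin"):
            chi_square_counts(5, 5, 5, 5)
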