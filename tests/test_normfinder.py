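"""NormFinder variance decomposition, stability values and pair selection."""

import numpy as np
import pandas as pd
import pytest

from qpcrnorm import best_pair, normfinder_rank, pair_stability
from qpcrnorm.errors import DomainError, InsufficientDataError
from qpcrnorm.normfinder import corrected_intra_variance

from conftest import make_quantities


# -- brute-force two-way ANOVA decomposition oracle ----------------------------
#
# Residuals computed by explicit loops; the gene-specific variances are then
# recovered by solving the exact moment equations E[v_i] = A sigma2 with
# A = (1 - 2/k) I + J / k^2, instead of the implementation's closed form.

def oracle_sigma2(z):
    k, n = z.shape
    r = np.empty_like(z)
    grand = z.mean()
    for i in range(k):
        for j in range(n):
            r[i, j] = z[i, j] - z[i, :].mean() - z[:, j].mean() + grand
    v = np.array([(r[i] ** 2).sum() / (n - 1) for i in range(k)])
    a = (1 - 2 / k) * np.eye(k) + np.ones((k, k)) / k**2
    return np.linalg.solve(a, v)


def log2_quantities(y, groups):
    """Build a QuantityMatrix whose log2() equals the given genes x samples y."""
    cols = {f"R{i}_utr": (2.0 ** y[i]).tolist() for i in range(y.shape[0])}
    return make_quantities(cols, groups=groups)


class TestVarianceDecomposition:
    def test_matches_anova_oracle_on_fixed_small_matrix(self):
        z = np.array(
            [
                [1.0, 1.2, 0.9, 1.1, 1.05, 0.95],
                [2.0, 2.5, 1.8, 2.2, 2.4, 1.9],
                [0.5, 0.1, 0.6, 0.2, 0.3, 0.55],
            ]
        )
        est = corrected_intra_variance(z)
        assert np.max(np.abs(est - oracle_sigma2(z))) < 1e-10

    def test_matches_anova_oracle_on_random_matrices(self, rng):
        for _ in range(10):
            k, n = rng.integers(3, 9), rng.integers(3, 12)
            z = rng.normal(0, 1, size=(k, n))
            est = corrected_intra_variance(z)
            assert np.max(np.abs(est - oracle_sigma2(z))) < 1e-10

    def test_per_group_variances_in_result(self, rng):
        y = rng.normal(0, 0.3, size=(4, 8))
        groups = ["G1"] * 4 + ["G2"] * 4
        res = normfinder_rank(log2_quantities(y, groups), mode="multi_group")
        for gi, g in enumerate(["G1", "G2"]):
            z = y[:, 4 * gi : 4 * gi + 4]
            expected = np.clip(oracle_sigma2(z), 0, None)
            assert np.max(np.abs(res.intra_var[g].to_numpy() - expected)) < 1e-10


class TestSingleGroup:
    def test_zero_residual_gene_is_most_stable(self, rng):
        n = 50
        sample_effect = rng.normal(0, 1, n)
        y = np.vstack(
            [sample_effect + 0.7]                         # pure sample effect + const
            + [
                sample_effect + rng.normal(0, sd, n)
                for sd in (0.4, 0.5, 0.6, 0.7, 0.8)
            ]
        )
        res = normfinder_rank(log2_quantities(y, ["G1"] * n), mode="single_group")
        assert res.best_region == "R0_utr"
        assert (res.inter_dev.to_numpy() == 0).all()

    def test_ranking_equals_residual_variance_ranking(self, rng):
        for _ in range(5):
            y = rng.normal(0, 1, size=(6, 9))
            res = normfinder_rank(log2_quantities(y, ["G1"] * 9), mode="single_group")
            centered = y - y.mean(axis=0, keepdims=True)  # remove sample means
            resid = centered - centered.mean(axis=1, keepdims=True)
            rv = pd.Series(
                (resid**2).sum(axis=1), index=[f"R{i}_utr" for i in range(6)]
            )
            # corrected estimate is an increasing affine map of the raw
            # residual variance, so orderings must coincide
            assert res.ranking == sorted(rv.index, key=lambda r: (rv[r], r))


class TestMultiGroup:
    def test_group_shifted_region_ranked_last(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n_per = 5
            y = rng.normal(0, 0.05, size=(6, 2 * n_per))
            y[3, n_per:] += 1.0  # +1 log2 shift in group 2 only
            groups = ["G1"] * n_per + ["G2"] * n_per
            res = normfinder_rank(log2_quantities(y, groups), mode="multi_group")
            hits += res.ranking[-1] == "R3_utr"
        assert hits >= 29

    def test_stability_invariant_to_per_sample_scaling(self, rng):
        y = rng.normal(0, 0.4, size=(5, 8))
        groups = ["G1"] * 4 + ["G2"] * 4
        res1 = normfinder_rank(log2_quantities(y, groups), mode="multi_group")
        y2 = y + rng.normal(0, 3, size=(1, 8))  # arbitrary per-sample shifts
        res2 = normfinder_rank(log2_quantities(y2, groups), mode="multi_group")
        assert np.allclose(res1.stability, res2.stability, atol=1e-9)

    def test_rho_increases_with_added_noise(self):
        rhos = []
        for sigma in (0.05, 0.2, 0.5):
            vals = []
            for seed in range(30):
                rng = np.random.default_rng(seed)
                y = rng.normal(0, 0.05, size=(5, 10))
                y[0] += np.random.default_rng(1000 + seed).normal(0, sigma, 10)
                groups = ["G1"] * 5 + ["G2"] * 5
                res = normfinder_rank(log2_quantities(y, groups), mode="multi_group")
                vals.append(res.stability["R0_utr"])
            rhos.append(np.mean(vals))
        assert rhos[0] < rhos[1] < rhos[2]

    def test_groups_sum_of_deviations_is_zero(self, rng):
        y = rng.normal(0, 0.5, size=(6, 9))
        groups = ["G1"] * 3 + ["G2"] * 3 + ["G3"] * 3
        res = normfinder_rank(log2_quantities(y, groups), mode="multi_group")
        assert np.allclose(res.inter_dev.sum(axis=0), 0.0, atol=1e-12)

    def test_shrunk_deviation_recovers_true_shift_at_large_n(self):
        # true centred deviation of a +delta shift in group 2 of 2, k genes:
        # gene centring leaves delta*(1-1/k), group centring halves it per group
        delta, k, n_per = 1.0, 6, 50
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.normal(0, 0.2, size=(k, 2 * n_per))
            y[2, n_per:] += delta
            groups = ["G1"] * n_per + ["G2"] * n_per
            res = normfinder_rank(log2_quantities(y, groups), mode="multi_group")
            true_d = delta * (1 - 1 / k) / 2
            errs.append(abs(abs(res.shrunk_dev.loc["R2_utr", "G2"]) - true_d) / true_d)
        assert np.mean(errs) < 0.10

    def test_small_group_errors_name_the_group(self, rng):
        y = rng.normal(0, 0.3, size=(4, 5))
        groups = ["G1"] * 4 + ["G2"]
        with pytest.raises(InsufficientDataError, match="G2"):
            normfinder_rank(log2_quantities(y, groups), mode="multi_group")

    def test_unknown_mode_rejected(self, rng):
        y = rng.normal(0, 0.3, size=(3, 4))
        with pytest.raises(DomainError):
            normfinder_rank(log2_quantities(y, ["G1"] * 4), mode="grouped")


class TestBestPair:
    def two_group_result(self, y):
        n = y.shape[1] // 2
        groups = ["G1"] * n + ["G2"] * n
        return normfinder_rank(log2_quantities(y, groups), mode="multi_group")

    def test_opposite_deviations_cancel(self):
        rng = np.random.default_rng(3)
        n = 8
        y = rng.normal(0, 0.05, size=(5, 2 * n))
        y[0, n:] += 0.8   # up in group 2
        y[1, n:] -= 0.8   # down in group 2
        res = self.two_group_result(y)
        s_pair = pair_stability(res, "R0_utr", "R1_utr")
        assert s_pair < res.stability["R0_utr"]
        assert s_pair < res.stability["R1_utr"]
        a, b, s = best_pair(res)
        assert {a, b} == {"R0_utr", "R1_utr"}
        assert s == pytest.approx(s_pair)

    def test_pair_symmetry(self, rng):
        y = rng.normal(0, 0.3, size=(4, 8))
        res = self.two_group_result(y)
        assert pair_stability(res, "R0_utr", "R2_utr") == pytest.approx(
            pair_stability(res, "R2_utr", "R0_utr")
        )

    def test_iid_pair_is_single_over_sqrt2(self):
        ratios = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = rng.normal(0, 0.3, size=(6, 12))
            res = self.two_group_result(y)
            mean_single = res.stability.mean()
            pairs = [
                pair_stability(res, a, b)
                for i, a in enumerate(res.stability.index)
                for b in res.stability.index[i + 1 :]
            ]
            ratios.append(np.mean(pairs) / mean_single)
        assert np.mean(ratios) == pytest.approx(1 / np.sqrt(2), rel=0.10)

    def test_single_group_mode_unsupported(self, rng):
        y = rng.normal(0, 0.3, size=(4, 6))
        res = normfinder_rank(log2_quantities(y, ["G1"] * 6), mode="single_group")
        with pytest.raises(DomainError):
            best_pair(res)
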