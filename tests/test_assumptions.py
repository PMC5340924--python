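"""Unidimensionality, local independence and monotonicity checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal, norm

import gradedcat as gc
from gradedcat.assumptions import (
    bvn_cdf,
    flag_local_dependence,
    polychoric_pair,
)
from gradedcat.responses import ResponseMatrix


def _rm(arr, scale="s"):
    arr = np.asarray(arr, dtype=float)
    frame = pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])],
                         columns=[f"i{j}" for j in range(arr.shape[1])])
    return ResponseMatrix(frame, {c: scale for c in frame.columns})


class TestBivariateNormal:
    @pytest.mark.parametrize("rho", [-0.95, -0.5, 0.0, 0.3, 0.7, 0.99])
    def test_matches_scipy_oracle(self, rho):
        rng = np.random.default_rng(0)
        pts = list(rng.normal(scale=1.5, size=(25, 2)))
        pts += [(0.0, 0.7), (0.7, 0.0), (0.0, 0.0), (0.0, -0.7), (-0.7, 0.0)]
        for h, k in pts:
            ref = multivariate_normal.cdf([h, k], cov=[[1, rho], [rho, 1]])
            assert float(bvn_cdf(h, k, rho)) == pytest.approx(ref, abs=1e-9)

    def test_infinite_limits(self):
        assert float(bvn_cdf(np.inf, 0.3, 0.5)) == pytest.approx(norm.cdf(0.3))
        assert float(bvn_cdf(-np.inf, 0.3, 0.5)) == 0.0
        assert float(bvn_cdf(np.inf, np.inf, 0.5)) == 1.0


class TestPolychoric:
    def test_diagonal_is_one_and_symmetric(self, small_rm):
        R = gc.polychoric_matrix(small_rm, "scale")
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(4)
        bank = gc.generate_bank(2, seed=5)
        th = rng.standard_normal((5000, 2))  # independent traits per item
        rm = gc.simulate_responses(bank, th, seed=6)
        R = gc.polychoric_matrix(rm, "scale")
        assert abs(R.iloc[0, 1]) < 0.05

    def test_worked_2x2_table_matches_grid_search_oracle(self):
        table = np.array([[310, 120], [90, 480]], dtype=float)
        # independent oracle: exhaustive scan of the bivariate-normal
        # likelihood over a fine rho grid, thresholds fixed from margins
        n = table.sum()
        t_r = norm.ppf(table.sum(axis=1).cumsum()[:-1] / n)
        t_c = norm.ppf(table.sum(axis=0).cumsum()[:-1] / n)
        grid = np.linspace(-0.99, 0.99, 3961)
        best, best_ll = 0.0, -np.inf
        for rho in grid:
            cov = [[1, rho], [rho, 1]]
            p11 = multivariate_normal.cdf([t_r[0], t_c[0]], cov=cov)
            p1c = norm.cdf(t_r[0])
            pc1 = norm.cdf(t_c[0])
            cells = np.array([[p11, p1c - p11],
                              [pc1 - p11, 1 - p1c - pc1 + p11]])
            ll = (table * np.log(np.clip(cells, 1e-12, None))).sum()
            if ll > best_ll:
                best, best_ll = rho, ll
        assert polychoric_pair(table) == pytest.approx(best, abs=1e-3)

    def test_permutation_equivariance(self, small_rm):
        R = gc.polychoric_matrix(small_rm, "scale")
        cols = small_rm.item_ids[::-1]
        rev = ResponseMatrix(small_rm.codes[cols], {c: "scale" for c in cols})
        R2 = gc.polychoric_matrix(rev, "scale")
        assert np.allclose(R.loc[cols, cols].to_numpy(), R2.to_numpy(),
                           atol=1e-10)

    def test_degenerate_item_named(self):
        arr = np.column_stack([np.ones(30), np.arange(30) % 3])
        with pytest.raises(ValueError, match="i0"):
            gc.polychoric_matrix(_rm(arr), "s")


class TestOneFactorFit:
    def test_exact_one_factor_truth(self):
        lam = np.full(8, 0.7)
        S = np.outer(lam, lam)
        np.fill_diagonal(S, 1.0)
        loadings, fit, resid = gc.fit_one_factor(S, n=500)
        assert np.max(np.abs(resid)) < 1e-6
        assert fit.cfi == pytest.approx(1.0)
        assert fit.srmr < 1e-6
        assert np.allclose(np.abs(loadings), 0.7, atol=1e-6)

    def test_identity_matrix_null_structure(self):
        loadings, fit, resid = gc.fit_one_factor(np.eye(6), n=500)
        assert np.max(np.abs(loadings)) < 1e-3
        assert fit.srmr < 1e-3
        assert fit.rmsea == pytest.approx(0.0, abs=1e-8)

    def test_two_factor_data_fits_worse_than_one_factor_truth(self):
        rng = np.random.default_rng(11)
        n = 2000
        f1, f2 = rng.standard_normal((2, n))
        one = np.column_stack(
            [0.8 * f1 + np.sqrt(1 - 0.64) * rng.standard_normal(n)
             for _ in range(6)])
        two = np.column_stack(
            [0.8 * (f1 if j < 3 else f2)
             + np.sqrt(1 - 0.64) * rng.standard_normal(n) for j in range(6)])
        S1 = np.corrcoef(one, rowvar=False)
        S2 = np.corrcoef(two, rowvar=False)
        _, fit1, _ = gc.fit_one_factor(S1, n=n)
        _, fit2, _ = gc.fit_one_factor(S2, n=n)
        assert fit2.rmsea > fit1.rmsea
        assert fit2.srmr > fit1.srmr

    def test_sample_size_contract(self):
        with pytest.raises(ValueError):
            gc.fit_one_factor(np.eye(6), n=6)


class TestLocalDependence:
    def test_small_residuals_give_empty_list(self):
        R = np.full((4, 4), 0.05)
        np.fill_diagonal(R, 0.0)
        assert flag_local_dependence(R) == []

    def test_threshold_zero_returns_every_positive_pair(self):
        R = np.array([[0, 0.1, -0.2], [0.1, 0, 0.3], [-0.2, 0.3, 0]])
        pairs = flag_local_dependence(R, threshold=0.0)
        assert [(a, b) for a, b, _ in pairs] == [(1, 2), (0, 1)]

    def test_constructed_correlated_error_pair_is_unique_flag(self):
        # two items share an extra factor beyond the scale trait
        rng = np.random.default_rng(7)
        bank = gc.generate_bank(8, alpha_range=(1.5, 2.5), seed=8)
        n = 2000
        theta = rng.standard_normal(n)
        shared = rng.standard_normal(n)
        th = np.tile(theta[:, None], (1, 8))
        mixed = (theta + shared) / np.sqrt(2.0)
        th[:, 2] = mixed
        th[:, 5] = mixed
        rm = gc.simulate_responses(bank, th, seed=9)
        R = gc.polychoric_matrix(rm, "scale")
        _, _, resid = gc.fit_one_factor(R, n=n)
        pairs = flag_local_dependence(resid)
        assert [(a, b) for a, b, _ in pairs] == [("it03", "it06")]

    def test_requires_symmetric_matrix(self):
        with pytest.raises(ValueError):
            flag_local_dependence(np.array([[0, 1], [0.5, 0]]))


class TestCountItemPairs:
    @pytest.mark.parametrize("sizes, expected", [([2], 1), ([3, 4], 9)])
    def test_small_cases(self, sizes, expected):
        assert gc.count_item_pairs(sizes) == expected

    @given(st.lists(st.integers(1, 20), min_size=1, max_size=6))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_enumeration(self, sizes):
        brute = 0
        for k in sizes:
            brute += sum(1 for a in range(k) for b in range(a + 1, k))
        assert gc.count_item_pairs(sizes) == brute

    def test_rejects_zero_size(self):
        with pytest.raises(ValueError):
            gc.count_item_pairs([0, 3])


class TestScalability:
    def test_guttman_data_gives_unit_coefficients(self):
        total = np.arange(30)
        X = np.column_stack([
            np.digitize(total, [10, 20]),
            np.digitize(total, [12, 22]),
            np.digitize(total, [8, 18]),
        ])
        res = gc.scalability(_rm(X), "s")
        assert all(h == pytest.approx(1.0) for h in res.pairwise_h.values())
        assert res.scale_h == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(13)
        X = rng.integers(0, 3, size=(5000, 4))
        res = gc.scalability(_rm(X), "s")
        assert all(abs(h) < 0.05 for h in res.item_h.values())

    def test_worked_matrix_matches_brute_force_oracle(self):
        X = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0],
             [2, 1, 1], [2, 2, 1], [1, 2, 2], [2, 2, 2]]
        # replicating rows leaves every H ratio unchanged and satisfies the
        # minimum-sample precondition
        res = gc.scalability(_rm(np.tile(np.array(X), (3, 1))), "s")
        # frozen from explicit cov / comonotonic-sort cov_max computation
        assert res.pairwise_h[("i0", "i1")] == pytest.approx(0.7241379310344829)
        assert res.pairwise_h[("i0", "i2")] == pytest.approx(0.4666666666666667)
        assert res.pairwise_h[("i1", "i2")] == pytest.approx(1.0)
        assert res.scale_h == pytest.approx(0.7419354838709679)

    def test_pairwise_h_bounded_above_by_one(self, small_rm):
        res = gc.scalability(small_rm, "scale")
        assert all(h <= 1.0 + 1e-12 for h in res.pairwise_h.values())
        assert all(h >= 0 for h in res.item_h.values())

    def test_grm_scale_is_monotone_by_convention(self, small_rm):
        assert gc.scalability(small_rm, "scale").monotone

    def test_constant_item_reported_undefined(self):
        arr = np.column_stack([np.ones(40), np.arange(40) % 3,
                               np.arange(40) % 2])
        res = gc.scalability(_rm(arr), "s")
        assert res.undefined == ["i0"]


class TestRestScoreTraces:
    @staticmethod
    def _deterministic_scale(flip: bool):
        # four monotone 0-2 items build the rest score; the probed item is a
        # deterministic step function of the same severity gradient
        base = np.repeat(np.arange(10), 10)
        rest_items = [np.clip(base - k, 0, 2) for k in range(4)]
        item = np.digitize(base, [4, 7])
        if flip:
            item = 2 - item
        return np.column_stack([item] + rest_items)

    def test_monotone_deterministic_item(self):
        tab = gc.rest_score_traces(_rm(self._deterministic_scale(False)),
                                   "s", "i0", min_group=5)
        assert not tab["violation"].any()

    def test_antimonotone_item_flags_violation(self):
        tab = gc.rest_score_traces(_rm(self._deterministic_scale(True)),
                                   "s", "i0", min_group=5)
        assert tab["violation"].sum() >= 1

    def test_grm_data_shows_manifest_monotonicity(self):
        # under the generating model, rest-score trace lines rise
        bank = gc.generate_bank(8, seed=17)
        th = np.random.default_rng(18).standard_normal(5000)
        rm = gc.simulate_responses(bank, th, seed=19)
        clean = 0
        for iid in rm.item_ids:
            tab = gc.rest_score_traces(rm, "scale", iid, min_group=50)
            clean += int(not tab["significant_violation"].any())
        assert clean >= 0.95 * len(rm.item_ids)

    def test_bins_respect_min_group(self, small_rm):
        tab = gc.rest_score_traces(small_rm, "scale", "it01", min_group=40)
        assert (tab["n"] >= 40).all()
        assert tab["n"].sum() == small_rm.n_persons
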