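"""Tetrachoric estimation, PD smoothing, probability-based covariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal, norm

from mdcfa import (
    BinaryDataset,
    MissingDesign,
    PopulationModel,
    ensure_pd,
    estimate_threshold,
    generate_dataset,
    inject_missing,
    probability_based_covariance,
    replace_missing_with_zero,
    tetrachoric_matrix,
    tetrachoric_pair,
)
from mdcfa._bvn import bvn_cdf
from mdcfa.datagen import MISSING
from mdcfa.tetrachoric import DegenerateMarginError, RHO_BOUND


class TestBivariateNormal:
    def test_matches_scipy_quadrature_oracle(self, rng):
        for _ in range(50):
            h, k = rng.normal(0, 1.5, size=2)
            r = rng.uniform(-0.98, 0.98)
            ref = multivariate_normal(cov=[[1, r], [r, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, r) == pytest.approx(ref, abs=1e-9)

    def test_zero_thresholds_closed_form(self):
        # Phi2(0, 0; rho) = 1/4 + arcsin(rho) / (2 pi)
        for r in (-0.9, -0.3, 0.0, 0.5, 0.95):
            assert bvn_cdf(0.0, 0.0, r) == pytest.approx(
                0.25 + np.arcsin(r) / (2 * np.pi), abs=1e-12
            )

    def test_monotone_in_rho(self):
        rhos = np.linspace(-0.99, 0.99, 41)
        vals = bvn_cdf(0.3, -0.6, rhos)
        assert (np.diff(vals) > 0).all()


class TestThreshold:
    @pytest.mark.parametrize(
        "p1, tau", [(0.5, 0.0), (0.8413, -1.0), (0.025, 1.96)]
    )
    def test_inverse_normal_values(self, p1, tau):
        assert estimate_threshold(p1) == pytest.approx(tau, abs=5e-3)

    @pytest.mark.parametrize("p1", [0.0, 1.0])
    def test_degenerate_margin_rejected(self, p1):
        with pytest.raises(DegenerateMarginError):
            estimate_threshold(p1)


def _grid_oracle(table, step=1e-4):
    """Brute-force two-step likelihood maximization over a dense rho grid."""
    t = np.asarray(table, dtype=float)
    if (t == 0).any():
        t = t + 0.5
    n11, n10, n01, n00 = t[0, 0], t[0, 1], t[1, 0], t[1, 1]
    n = t.sum()
    p1i, p1j = (n11 + n10) / n, (n11 + n01) / n
    ti, tj = norm.isf(p1i), norm.isf(p1j)
    grid = np.arange(-0.9990, 0.9990 + step / 2, step)
    pi11 = np.clip(bvn_cdf(-ti, -tj, grid), 1e-12, None)
    pi10 = np.clip(p1i - pi11, 1e-12, None)
    pi01 = np.clip(p1j - pi11, 1e-12, None)
    pi00 = np.clip(1 - p1i - p1j + pi11, 1e-12, None)
    ll = n11 * np.log(pi11) + n10 * np.log(pi10) + n01 * np.log(pi01) + n00 * np.log(pi00)
    return grid[np.argmax(ll)]


class TestTetrachoricPair:
    def test_perfect_association_hits_upper_bound(self):
        rho, diag = tetrachoric_pair([[50, 0], [0, 50]])
        assert rho == pytest.approx(RHO_BOUND)
        assert diag["at_bound"] and diag["corrected"]

    def test_independence_gives_zero(self):
        rho, _ = tetrachoric_pair([[25, 25], [25, 25]])
        assert rho == pytest.approx(0.0, abs=1e-10)

    def test_grid_search_oracle_equivalence_on_random_tables(self, rng):
        for _ in range(50):
            table = rng.integers(1, 80, size=(2, 2))
            rho, _ = tetrachoric_pair(table)
            assert abs(rho - _grid_oracle(table)) < 1e-3

    @given(
        a=st.integers(1, 100),
        b=st.integers(1, 100),
        c=st.integers(1, 100),
        d=st.integers(1, 100),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_column_swap_negates_rho(self, a, b, c, d):
        rho, _ = tetrachoric_pair([[a, b], [c, d]])
        neg, _ = tetrachoric_pair([[b, a], [d, c]])
        assert abs(rho) <= RHO_BOUND
        assert rho == pytest.approx(-neg, abs=1e-8)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateMarginError):
            tetrachoric_pair([[0, 0], [30, 40]])


class TestTetrachoricMatrix:
    def test_consistency_for_latent_correlation(self):
        # large single sample: off-diagonals near the generating 0.1225
        ds = generate_dataset(PopulationModel(n=20_000), seed=2)
        corr = tetrachoric_matrix(ds)
        off = corr.matrix[np.triu_indices(20, k=1)]
        assert abs(off.mean() - 0.1225) < 0.02
        assert np.allclose(corr.matrix, corr.matrix.T)
        assert np.allclose(np.diag(corr.matrix), 1.0)
        assert np.abs(corr.matrix).max() <= 1.0
        assert np.allclose(corr.thresholds, 0.0, atol=0.05)

    def test_duplicated_column_at_bound(self):
        vals = np.array([[1, 1, 0], [0, 0, 1], [1, 1, 1], [0, 0, 0]] * 5, dtype=np.int8)
        corr = tetrachoric_matrix(BinaryDataset(vals))
        # zero cells get the continuity correction, so just below the bound
        assert corr.matrix[0, 1] > 0.95

    def test_two_items_minimal(self):
        vals = np.array([[1, 0], [0, 1], [1, 1], [0, 0]] * 4, dtype=np.int8)
        corr = tetrachoric_matrix(BinaryDataset(vals))
        assert corr.matrix.shape == (2, 2)

    def test_degenerate_margin_names_item(self):
        vals = np.ones((30, 3), dtype=np.int8)
        vals[:, 0] = np.arange(30) % 2
        vals[:, 2] = (np.arange(30) + 1) % 2
        with pytest.raises(DegenerateMarginError, match="item02"):
            tetrachoric_matrix(BinaryDataset(vals))

    def test_zero_replacement_shrinks_design_margins(self):
        ds = generate_dataset(PopulationModel(), seed=3)
        out = replace_missing_with_zero(
            inject_missing(ds, MissingDesign(tuple(range(11, 21)), 0.6, seed=1))
        )
        assert out.is_complete
        shrink = out.values[:, 10:].mean(axis=0) / ds.values[:, 10:].mean(axis=0)
        assert np.abs(shrink - 0.4).max() < 0.05

    def test_replace_missing_is_identity_on_complete_data(self, complete_500x20):
        out = replace_missing_with_zero(complete_500x20)
        assert np.array_equal(out.values, complete_500x20.values)

    def test_single_missing_cell_becomes_zero(self):
        vals = np.array([[1, 0], [MISSING, 1]], dtype=np.int8)
        out = replace_missing_with_zero(BinaryDataset(vals))
        assert out.values[1, 0] == 0
        assert out.values[0, 0] == 1

    def test_monotone_attenuation_with_rate(self):
        means = []
        for rate in (0.2, 0.4, 0.6):
            mats = []
            for rep in range(8):
                ds = generate_dataset(PopulationModel(), seed=100 + rep)
                design = MissingDesign(tuple(range(11, 21)), rate, seed=rep)
                mats.append(tetrachoric_matrix(inject_missing(ds, design)).matrix)
            cross = np.mean(mats, axis=0)[:10, 10:]
            means.append(cross.mean())
        assert means[0] > means[1] > means[2]


class TestEnsurePD:
    def test_identity_unchanged(self):
        out, ridge = ensure_pd(np.eye(4))
        assert ridge == 0.0
        assert np.array_equal(out, np.eye(4))

    def test_near_singular_but_pd_unchanged(self):
        mat = np.array([[1.0, 0.9999], [0.9999, 1.0]])
        out, ridge = ensure_pd(mat, floor=1e-6)
        assert ridge == 0.0
        assert np.array_equal(out, mat)

    def test_indefinite_matrix_smoothed_to_floor(self):
        mat = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        out, ridge = ensure_pd(mat, floor=1e-6)
        assert ridge > 0
        assert np.linalg.eigvalsh(out).min() >= 1e-6 - 1e-12
        assert np.allclose(np.diag(out), 1.0)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-1, 1, size=(4, 4))
        mat = (a + a.T) / 2
        np.fill_diagonal(mat, 1.0)
        once, _ = ensure_pd(mat)
        twice, ridge2 = ensure_pd(once)
        assert ridge2 <= 1e-10
        assert np.allclose(once, twice, atol=1e-10)


class TestProbabilityBasedCovariance:
    def test_independent_fair_items_near_zero(self, rng):
        vals = rng.integers(0, 2, size=(5000, 4)).astype(np.int8)
        cov = probability_based_covariance(BinaryDataset(vals))
        off = cov[np.triu_indices(4, k=1)]
        assert np.abs(off).max() < 0.03

    def test_identical_fair_columns_give_quarter(self):
        col = np.array([1, 0] * 10, dtype=np.int8)
        cov = probability_based_covariance(BinaryDataset(np.column_stack([col, col])))
        assert cov[0, 1] == pytest.approx(0.25)
        assert cov[0, 0] == pytest.approx(0.25)

    def test_joint_minus_product_toy(self):
        # margins 0.6 and 0.5, joint 0.4 -> 0.4 - 0.3 = 0.10
        a = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0], dtype=np.int8)
        b = np.array([1, 1, 1, 1, 0, 0, 1, 0, 0, 0], dtype=np.int8)
        cov = probability_based_covariance(BinaryDataset(np.column_stack([a, b])))
        assert cov[0, 1] == pytest.approx(0.10)

    def test_missing_counts_as_not_one(self):
        vals = np.array([[1, 1], [MISSING, 1], [0, 0], [1, 0]], dtype=np.int8)
        ds = BinaryDataset(vals)
        cov = probability_based_covariance(ds)
        # Pr(A=1)=0.5, Pr(B=1)=0.5, joint=0.25
        assert cov[0, 1] == pytest.approx(0.25 - 0.25)


class TestCorrelationIO:
    def test_square_csv_round_trip(self, tmp_path, complete_500x20):
        corr = tetrachoric_matrix(complete_500x20)
        path = tmp_path / "corr.csv"
        corr.to_csv(path)
        back = type(corr).from_csv(path)
        assert np.allclose(back.matrix, corr.matrix, atol=1e-12)

    def test_lower_triangular_round_trip(self, tmp_path, complete_500x20):
        corr = tetrachoric_matrix(complete_500x20)
        path = tmp_path / "corr.lt"
        corr.to_lower_triangular(path, fmt="%.10f")
        back = type(corr).from_lower_triangular(path)
        assert np.allclose(back.matrix, corr.matrix, atol=1e-9)
        assert back.pd

    def test_thresholds_sidecar(self, tmp_path, complete_500x20):
        import pandas as pd

        corr = tetrachoric_matrix(complete_500x20)
        path = tmp_path / "tau.csv"
        corr.thresholds_to_csv(path)
        df = pd.read_csv(path)
        assert list(df["item"])[0] == "item01"
        assert np.allclose(df["threshold"], corr.thresholds)
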