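import numpy as np
import pandas as pd
import pytest

from specfluor.errors import ConfigError, FitError
from specfluor.indices import ALL_INDEX_TYPES, compute_index
from specfluor.search import (
    SearchGrid,
    candidate_matrix,
    enumerate_candidates,
    fit_univariate,
    overall_winners,
    search_matrix,
    search_optimal,
)

from conftest import make_matrix, smooth_random_spectra


def brute_force_best(spectra, y, index_type, grid):
    """Independent oracle: per-candidate polyfit over an explicit loop."""
    best = None
    for spec in enumerate_candidates(index_type, grid, spectra.wavelengths):
        spec = type(spec)(
            spec.index_type, spec.lambda1_nm, spec.lambda2_nm, spec.delta_nm,
            transform_tag=spectra.transform_tag,
        )
        x = compute_index(spectra, spec)
        keep = np.isfinite(x) & np.isfinite(y)
        if keep.mean() < 0.95 or keep.sum() < 3:
            continue
        xk, yk = x[keep], y[keep]
        if np.ptp(xk) == 0:
            continue
        coef = np.polyfit(xk, yk, 1)
        rss = float(np.sum((yk - np.polyval(coef, xk)) ** 2))
        n = keep.sum()
        aic = n * np.log(max(rss, 1e-300) / n) + 6
        if best is None or aic < best[0]:
            best = (aic, spec)
    return best


class TestEnumeration:
    GRID_WL = np.arange(400, 2401)

    def test_closed_form_counts_on_10nm_grid(self):
        grid = SearchGrid(step_nm=10)
        assert len(enumerate_candidates("R", grid, self.GRID_WL)) == 201
        assert len(enumerate_candidates("SR", grid, self.GRID_WL)) == 201 * 200
        for t in ("D", "ND", "ID"):
            assert len(enumerate_candidates(t, grid, self.GRID_WL)) == 201 * 200 // 2

    def test_offset_types_respect_range(self):
        grid = SearchGrid(step_nm=10)
        cands = enumerate_candidates("DDn", grid, self.GRID_WL)
        assert all(
            c.lambda1_nm - c.delta_nm >= 400 and c.lambda1_nm + c.delta_nm <= 2400
            for c in cands
        )
        assert not any(c.lambda1_nm == 400 for c in cands)
        # sum over d of (201 - 2d) grid positions
        assert len(cands) == sum(201 - 2 * d for d in range(1, 101))

    def test_unordered_pairs_listed_lambda1_first(self):
        grid = SearchGrid(step_nm=100)
        cands = enumerate_candidates("ND", grid, self.GRID_WL)
        assert all(c.lambda1_nm < c.lambda2_nm for c in cands)
        # lexicographic order backs the deterministic tie-break
        keys = [(c.lambda1_nm, c.lambda2_nm) for c in cands]
        assert keys == sorted(keys)


class TestFitUnivariate:
    def test_perfect_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        aic, r2, slope, intercept = fit_univariate(x, 2 * x + 1)
        assert (r2, slope, intercept) == (1.0, pytest.approx(2.0), pytest.approx(1.0))

    def test_hand_computed_toy_set(self):
        # {(0,0),(1,1),(2,2.1)}: slope 1.05, intercept -1/60, RSS = 1/600
        aic, r2, slope, intercept = fit_univariate([0, 1, 2], [0, 1, 2.1])
        assert slope == pytest.approx(1.05)
        assert intercept == pytest.approx(-1 / 60)
        assert aic == pytest.approx(3 * np.log((1 / 600) / 3) + 6)
        assert r2 == pytest.approx(1 - (1 / 600) / (331 / 150))

    def test_null_relationship_r2_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(2000), rng.standard_normal(2000)
        _, r2, _, _ = fit_univariate(x, y)
        assert r2 < 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(FitError):
            fit_univariate([1.0, 1.0, 1.0], [0, 1, 2])
        with pytest.raises(FitError):
            fit_univariate([np.nan, 1.0, 2.0, np.nan], [0, 1, 2, 3])


class TestSearchOptimal:
    def _spectra_and_target(self, seed=0, n=40):
        spectra = smooth_random_spectra(n, np.random.default_rng(seed), hi_nm=700)
        rng = np.random.default_rng(seed + 1)
        y = spectra.band(520) - spectra.band(660) + 0.01 * rng.standard_normal(n)
        return spectra, y

    @pytest.mark.parametrize("index_type", ALL_INDEX_TYPES)
    def test_matches_brute_force_oracle(self, index_type):
        spectra, y = self._spectra_and_target()
        grid = SearchGrid(step_nm=50)
        res = search_optimal(spectra, y, index_type, grid)
        oracle_aic, oracle_spec = brute_force_best(spectra, y, index_type, grid)
        assert res.index_spec == oracle_spec
        assert res.aic == pytest.approx(oracle_aic, abs=1e-8)

    def test_candidate_matrix_columns_match_specs(self):
        spectra, _ = self._spectra_and_target()
        grid = SearchGrid(step_nm=100)
        X, specs = candidate_matrix(spectra, "mND", grid)
        for j in (0, len(specs) // 2, len(specs) - 1):
            direct = compute_index(spectra, specs[j])
            np.testing.assert_allclose(X[:, j], direct, equal_nan=True, atol=1e-14)

    def test_swap_invariance_of_unordered_pairs(self):
        spectra, y = self._spectra_and_target()
        from specfluor.indices import IndexSpec

        x = compute_index(spectra, IndexSpec("ND", 500, lambda2_nm=600))
        a = fit_univariate(x, y)
        b = fit_univariate(-x, y)
        assert a[0] == pytest.approx(b[0], abs=1e-10)  # AIC unchanged
        assert a[1] == pytest.approx(b[1], abs=1e-12)

    def test_deterministic(self):
        spectra, y = self._spectra_and_target()
        r1 = search_optimal(spectra, y, "ND", SearchGrid(50))
        r2 = search_optimal(spectra, y, "ND", SearchGrid(50))
        assert r1 == r2

    def test_aic_winner_is_r2_winner_within_type(self):
        spectra, y = self._spectra_and_target()
        grid = SearchGrid(step_nm=50)
        X, _ = candidate_matrix(spectra, "D", grid)
        fits = [fit_univariate(X[:, j], y) for j in range(X.shape[1])]
        by_aic = min(range(len(fits)), key=lambda j: fits[j][0])
        by_r2 = max(range(len(fits)), key=lambda j: fits[j][1])
        assert by_aic == by_r2

    def test_constant_target_reports_zero_r2(self):
        spectra, _ = self._spectra_and_target()
        res = search_optimal(spectra, np.full(spectra.n_samples, 0.4), "D", SearchGrid(100))
        assert res.r_squared == 0.0

    def test_misaligned_target_rejected(self):
        spectra, y = self._spectra_and_target()
        with pytest.raises(ConfigError):
            search_optimal(spectra, y[:-1], "D")


class TestSearchMatrix:
    def test_all_cells_present(self, small_dataset):
        from specfluor import apply_transform, derive_table

        _, spectra, fluor = small_dataset
        params = derive_table(fluor)[["npq", "ql"]]
        by_transform = {
            t: apply_transform(spectra, t) for t in ("fod:0", "fod:0.5")
        }
        table = search_matrix(
            by_transform, params, spectra.group,
            index_types=("D", "ND"), grid=SearchGrid(step_nm=100),
        )
        assert len(table) == 2 * 2 * 2 * 2  # transform x type x param x group
        assert not table["skipped"].any()
        winners = overall_winners(table)
        assert len(winners) == 4
        assert (winners.groupby(["group", "parameter"]).size() == 1).all()

    def test_empty_transform_list_rejected(self, small_dataset):
        _, spectra, fluor = small_dataset
        with pytest.raises(ConfigError):
            search_matrix({}, pd.DataFrame(), spectra.group)
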