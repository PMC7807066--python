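"""Synthetic-landscape generator: determinism, autocorrelation, sampling law."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chisquare

from emusdm import (
    Grid,
    GridSurface,
    LandscapeSpec,
    PredictorStack,
    ScenarioShift,
    TrueNiche,
    generate_analogue_sightings,
    generate_predictor_stack,
    sample_occurrences,
    shift_climate,
    true_suitability,
)


def morans_i_lag1(values: np.ndarray) -> float:
    """Direct double-sum Moran's I with rook (lag-1) weights — oracle."""
    z = values - values.mean()
    n_rows, n_cols = values.shape
    num = 0.0
    w_sum = 0.0
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    num += z[r, c] * z[rr, cc]
                    w_sum += 1.0
    return (values.size / w_sum) * num / (z**2).sum()


def _spec(**kw) -> LandscapeSpec:
    base = dict(
        n_rows=20, n_cols=20, cell_size_km=10.0, layer_names=("a",), seed=0
    )
    base.update(kw)
    return LandscapeSpec(**base)


class TestGeneratePredictorStack:
    def test_same_seed_bit_identical(self):
        spec = _spec(layer_names=("a", "b"), autocorr_length_km=30.0, seed=5)
        s1 = generate_predictor_stack(spec)
        s2 = generate_predictor_stack(spec)
        for name in s1.names:
            np.testing.assert_array_equal(s1[name], s2[name])

    def test_layers_standardized_and_finite(self):
        stack = generate_predictor_stack(_spec(layer_names=("a", "b"), autocorr_length_km=(0.0, 50.0)))
        for _, arr in stack.items():
            assert np.all(np.isfinite(arr))
            assert abs(arr.mean()) < 1e-12
            assert abs(arr.std() - 1.0) < 1e-12

    def test_zero_autocorr_gives_near_zero_morans_i(self):
        vals = []
        for seed in range(10):
            stack = generate_predictor_stack(_spec(autocorr_length_km=0.0, seed=seed))
            vals.append(morans_i_lag1(stack["a"]))
        # white noise: lag-1 Moran's I ~ 0 within Monte-Carlo error
        assert abs(np.mean(vals)) < 0.05

    def test_longer_autocorr_strictly_larger_morans_i(self):
        means = []
        for length in (0.0, 20.0, 50.0):
            vals = [
                morans_i_lag1(
                    generate_predictor_stack(
                        _spec(autocorr_length_km=length, seed=seed)
                    )["a"]
                )
                for seed in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            _spec(n_rows=0)
        with pytest.raises(ValueError):
            _spec(layer_names=("a", "a"))
        with pytest.raises(ValueError):
            _spec(layer_names=())
        with pytest.raises(ValueError):
            _spec(autocorr_length_km=-1.0)


class TestTrueSuitability:
    def test_zero_niche_gives_half_everywhere(self, small_stack):
        niche = TrueNiche(intercept=0.0, coefficients={})
        suit = true_suitability(small_stack, niche)
        np.testing.assert_allclose(suit.values, 0.5)

    def test_large_intercept_saturates_towards_one(self, small_stack):
        lo = true_suitability(small_stack, TrueNiche(5.0, {"bio13": 1.0}))
        hi = true_suitability(small_stack, TrueNiche(15.0, {"bio13": 1.0}))
        assert np.all(hi.values > lo.values)
        assert hi.values.min() > 0.99

    def test_hand_evaluated_3x3(self):
        grid = Grid(3, 3, 1.0)
        a = np.arange(9, dtype=float).reshape(3, 3) / 10.0
        b = np.linspace(-1, 1, 9).reshape(3, 3)
        stack = PredictorStack(grid, {"a": a, "b": b})
        niche = TrueNiche(0.3, {"a": 1.5, "b": -0.7}, {"a": 0.5})
        expected = expit(0.3 + 1.5 * a - 0.7 * b + 0.5 * a**2)
        suit = true_suitability(stack, niche)
        np.testing.assert_allclose(suit.values, expected, atol=1e-14)

    def test_unknown_layer_rejected(self, small_stack):
        with pytest.raises(KeyError):
            true_suitability(small_stack, TrueNiche(0.0, {"nope": 1.0}))


class TestSampleOccurrences:
    def test_exact_count_and_inside_grid(self, small_truth, uniform_surface):
        df = sample_occurrences(small_truth, uniform_surface, 100, seed=1)
        assert len(df) == 100
        assert small_truth.grid.contains(df["lon"], df["lat"]).all()

    def test_uniform_weights_match_multinomial(self):
        grid = Grid(10, 10, 1.0)
        ones = GridSurface(grid, np.ones(grid.shape))
        df = sample_occurrences(ones, ones, 5000, seed=2, dirty_fraction=0.0)
        row, col = grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
        counts = np.bincount(row * grid.n_cols + col, minlength=grid.n_cells)
        assert chisquare(counts).pvalue > 0.01

    def test_zero_suitability_region_gets_no_points(self, small_grid):
        suit = np.ones(small_grid.shape)
        suit[:, : small_grid.n_cols // 2] = 0.0
        ones = GridSurface(small_grid, np.ones(small_grid.shape))
        df = sample_occurrences(GridSurface(small_grid, suit), ones, 500, seed=3, dirty_fraction=0.0)
        _, col = small_grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
        assert col.min() >= small_grid.n_cols // 2

    def test_all_zero_weights_error(self, small_grid):
        zero = GridSurface(small_grid, np.zeros(small_grid.shape))
        one = GridSurface(small_grid, np.ones(small_grid.shape))
        with pytest.raises(ValueError):
            sample_occurrences(zero, one, 10, seed=0)

    def test_dirty_fraction_injects_rule_violations(self, small_truth, uniform_surface):
        df = sample_occurrences(small_truth, uniform_surface, 200, seed=4, dirty_fraction=0.2)
        n_bad = (
            (df["coord_uncertainty_m"] > 5000).sum()
            + df["year"].isna().sum()
            + df["is_fossil"].sum()
            + df["is_absence_record"].sum()
        )
        assert n_bad >= 0.15 * 200  # outlier defects are not counted here


class TestShiftClimate:
    def test_empty_shift_is_identity(self, small_stack):
        out = shift_climate(small_stack, ScenarioShift())
        for name in small_stack.names:
            np.testing.assert_array_equal(out[name], small_stack[name])

    def test_additive_delta_moves_mean_exactly(self, small_stack):
        out = shift_climate(small_stack, ScenarioShift(additive_delta={"bio13": 2.0}))
        assert np.isclose(out["bio13"].mean(), small_stack["bio13"].mean() + 2.0)
        np.testing.assert_array_equal(out["bio15"], small_stack["bio15"])

    def test_affine_on_hand_written_layer(self):
        grid = Grid(2, 2, 1.0)
        stack = PredictorStack(grid, {"a": np.array([[1.0, 2.0], [3.0, 4.0]])})
        out = shift_climate(
            stack,
            ScenarioShift(additive_delta={"a": -1.0}, multiplicative_factor={"a": 2.0}),
        )
        np.testing.assert_allclose(out["a"], np.array([[1.0, 3.0], [5.0, 7.0]]))

    def test_unknown_layer_rejected(self, small_stack):
        with pytest.raises(KeyError):
            shift_climate(small_stack, ScenarioShift(additive_delta={"zzz": 1.0}))

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            ScenarioShift(multiplicative_factor={"a": 0.0})


class TestAnalogueSightings:
    def test_uniform_bias_uniform_pattern(self):
        grid = Grid(10, 10, 1.0)
        ones = GridSurface(grid, np.ones(grid.shape))
        df = generate_analogue_sightings(ones, 5000, seed=5)
        row, col = grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
        counts = np.bincount(row * grid.n_cols + col, minlength=grid.n_cells)
        assert chisquare(counts).pvalue > 0.01

    def test_point_mass_bias_concentrates_all_points(self, small_grid):
        bias = np.zeros(small_grid.shape)
        bias[4, 7] = 1.0
        df = generate_analogue_sightings(GridSurface(small_grid, bias), 50, seed=6)
        row, col = small_grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
        assert (row == 4).all() and (col == 7).all()

    def test_same_seed_identical(self, uniform_surface):
        a = generate_analogue_sightings(uniform_surface, 40, seed=9)
        b = generate_analogue_sightings(uniform_surface, 40, seed=9)
        assert a.equals(b)
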