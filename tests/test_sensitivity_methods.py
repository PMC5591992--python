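"""The four sensitivity estimators against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from iqm_sense.sensitivity_methods import (
    DegenerateTrialSetError,
    TrialObservation,
    TrialSet,
    analyze_trial_set,
    brute_force_si,
    scatter_gradient,
    src,
    var_first_order,
)


def make_trial_set(x, y, x0=10.0, y0=10.0, segment="test") -> TrialSet:
    trials = tuple(
        TrialObservation(level_mm=1.0, trial_index=i, area_cm2=float(xi), signal=float(yi))
        for i, (xi, yi) in enumerate(zip(x, y))
    )
    return TrialSet(
        segment=segment, reference_area_cm2=x0, reference_signal=y0, trials=trials
    )


@pytest.fixture
def linear_set(rng) -> TrialSet:
    """Noise-free S = 2*SA + 1 over 30 spread-out trials."""
    x = rng.uniform(5, 15, size=30)
    return make_trial_set(x, 2 * x + 1, x0=10.0, y0=21.0)


class TestScatterGradient:
    def test_exact_line_recovered(self, linear_set):
        res = scatter_gradient(linear_set)
        assert res.global_index == pytest.approx(2.0, rel=1e-12)
        assert res.diagnostics["intercept"] == pytest.approx(1.0, rel=1e-10)
        assert res.diagnostics["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_signal_gives_zero_slope(self, rng):
        x = rng.uniform(5, 15, size=30)
        res = scatter_gradient(make_trial_set(x, np.full(30, 3.0)))
        assert res.global_index == pytest.approx(0.0, abs=1e-12)

    def test_identical_areas_degenerate(self):
        with pytest.raises(DegenerateTrialSetError):
            scatter_gradient(make_trial_set([2.0] * 10, range(10)))

    def test_matches_normal_equations_oracle(self, rng):
        # independent oracle: explicit normal-equations solve
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.uniform(1, 50, size=n)
            y = rng.normal(size=n) + 0.3 * x
            if np.ptp(x) == 0:
                continue
            slope = scatter_gradient(make_trial_set(x, np.abs(y) + 1)).global_index
            yy = np.abs(y) + 1
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(X.T @ X, X.T @ yy)
            assert slope == pytest.approx(beta[1], rel=1e-10)


class TestBruteForce:
    def test_identity_response_gives_unit_indices(self, rng):
        x = rng.uniform(5, 15, size=30)
        res = brute_force_si(make_trial_set(x, x, x0=10.0, y0=10.0))
        defined = ~np.isnan(res.per_trial)
        assert np.allclose(res.per_trial[defined], 1.0)
        assert res.global_index == pytest.approx(1.0)

    def test_constant_signal_gives_zero(self, rng):
        x = rng.uniform(5, 15, size=30)
        res = brute_force_si(make_trial_set(x, np.full(30, 7.0), x0=10.0, y0=7.0))
        defined = ~np.isnan(res.per_trial)
        assert np.allclose(res.per_trial[defined], 0.0)

    def test_unchanged_area_flagged_not_dropped(self):
        res = brute_force_si(make_trial_set([10.0, 11.0, 12.0], [1.0, 2.0, 3.0], x0=10.0, y0=1.0))
        assert np.isnan(res.per_trial[0])
        assert res.excluded == [0]
        assert len(res.per_trial) == 3

    def test_largest_indices_near_unaltered_area(self, rng):
        # noise over a flat response: |SI| ~ noise / |dSA|, peaks nearest SA0
        x = np.linspace(8, 12, 30)
        y = 10.0 + rng.normal(0, 0.1, size=30)
        res = brute_force_si(make_trial_set(x, y, x0=10.01, y0=10.0))
        order = np.argsort(np.abs(x - 10.01))
        top = np.nanargmax(np.abs(res.per_trial))
        assert top in order[:5]

    def test_all_undefined_yields_nan_global(self, caplog):
        res = brute_force_si(make_trial_set([10.0] * 5, range(5), x0=10.0, y0=0.0))
        assert np.isnan(res.global_index)
        assert len(res.excluded) == 5


class TestVarFirstOrder:
    def test_fully_explained_variance_near_one(self, rng):
        x = rng.uniform(5, 15, size=30)
        res = var_first_order(make_trial_set(x, x), n_bins=5)
        assert res.global_index >= 0.95
        assert res.global_index <= 1.0 + 1e-9

    def test_independent_output_near_zero(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.uniform(5, 15, size=30)
            y = r.uniform(5, 15, size=30)
            res = var_first_order(make_trial_set(x, y), n_bins=5)
            assert res.global_index < 0.2

    def test_matches_closed_form_additive_noise(self):
        # Y = X + eps: true index = Var(X) / (Var(X) + sigma^2)
        r = np.random.default_rng(77)
        n = 10_000
        x = r.uniform(0, 10, size=n)  # Var(X) = 100/12
        sigma = 1.5
        y = x + r.normal(0, sigma, size=n)
        res = var_first_order(make_trial_set(x, np.abs(y) + 1e-9, x0=5.0, y0=5.0), n_bins=50)
        truth = (100 / 12) / (100 / 12 + sigma**2)
        assert res.global_index == pytest.approx(truth, rel=0.10)

    def test_full_subset_per_trial_equals_global(self, rng):
        x = rng.uniform(5, 15, size=30)
        y = x + rng.normal(0, 0.5, size=30)
        res = var_first_order(make_trial_set(x, y), n_bins=5)
        last = int(np.argmax(x))
        assert res.per_trial[last] == pytest.approx(res.global_index, rel=1e-12)

    def test_small_prefixes_flagged(self, rng):
        x = rng.uniform(5, 15, size=30)
        res = var_first_order(make_trial_set(x, x), n_bins=5)
        smallest = np.argsort(x)[:3]
        assert all(np.isnan(res.per_trial[i]) for i in smallest)
        assert set(smallest) <= set(res.excluded)

    def test_affine_invariance(self, rng):
        x = rng.uniform(5, 15, size=30)
        y = x + rng.normal(0, 1, size=30)
        base = var_first_order(make_trial_set(x, np.abs(y)), n_bins=5).global_index
        scaled = var_first_order(
            make_trial_set(3 * x + 2, 5 * np.abs(y) + 7), n_bins=5
        ).global_index
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_zero_output_variance_degenerate(self):
        with pytest.raises(DegenerateTrialSetError):
            var_first_order(make_trial_set(np.arange(1, 31), np.full(30, 2.0)), n_bins=5)

    def test_too_few_trials_per_bin_degenerate(self):
        with pytest.raises(DegenerateTrialSetError):
            var_first_order(make_trial_set(np.arange(1, 8), np.arange(1, 8)), n_bins=5)


class TestSRC:
    def test_perfect_linear_gives_unit_src(self, rng):
        x = rng.uniform(5, 15, size=30)
        res = src(make_trial_set(x, 3 * x - 2, y0=28.0))
        assert res.global_index == pytest.approx(1.0, rel=1e-12)

    def test_antilinear_gives_minus_one(self, rng):
        x = rng.uniform(5, 15, size=30)
        res = src(make_trial_set(x, 50 - 2 * x))
        assert res.global_index == pytest.approx(-1.0, rel=1e-12)

    def test_src_squared_equals_r_squared(self, rng):
        for _ in range(20):
            x = rng.uniform(1, 20, size=25)
            y = 0.5 * x + rng.normal(0, 2, size=25)
            res = src(make_trial_set(x, np.abs(y) + 1))
            assert res.global_index**2 == pytest.approx(
                res.diagnostics["r_squared"], abs=1e-12
            )

    def test_per_trial_normalized_to_unit_max(self, rng):
        x = rng.uniform(5, 15, size=30)
        y = x + rng.normal(0, 0.5, size=30)
        res = src(make_trial_set(x, y))
        assert np.nanmax(np.abs(res.per_trial)) == pytest.approx(1.0)

    def test_largest_values_near_mean_area(self, rng):
        x = np.linspace(5, 15, 30)
        y = x + rng.normal(0, 0.3, size=30)
        res = src(make_trial_set(x, y))
        top = np.nanargmax(np.abs(res.per_trial))
        order = np.argsort(np.abs(x - x.mean()))
        assert top in order[:6]

    def test_zero_spread_degenerate(self):
        with pytest.raises(DegenerateTrialSetError):
            src(make_trial_set([3.0] * 10, np.arange(10.0)))


class TestCrossMethod:
    def test_noise_free_linear_agreement(self, linear_set):
        """All four estimators agree that a noise-free line is perfectly sensitive."""
        results = analyze_trial_set(linear_set)
        assert results["scatter_gradient"].global_index == pytest.approx(2.0, rel=1e-10)
        bf = results["brute_force"].per_trial
        assert np.allclose(bf[~np.isnan(bf)], 2.0)
        assert results["var_first_order"].global_index >= 0.95
        assert abs(results["src"].global_index) == pytest.approx(1.0, rel=1e-10)


class TestTrialSet:
    def test_from_dataframe_round_trip(self):
        df = pd.DataFrame(
            {
                "segment": ["s"] * 4,
                "level_mm": [0.0, 1.0, 1.0, 2.0],
                "trial": [0, 0, 1, 0],
                "area_cm2": [9.0, 8.9, 9.1, 9.3],
                "signal": [1.0, 0.99, 1.01, 1.03],
            }
        )
        ts = TrialSet.from_dataframe(df, "s")
        assert ts.reference_area_cm2 == 9.0
        assert ts.n == 3
        assert ts.trials[2].level_mm == 2.0

    def test_missing_reference_rejected(self):
        df = pd.DataFrame(
            {"segment": ["s"], "level_mm": [1.0], "trial": [0], "area_cm2": [9.0], "signal": [1.0]}
        )
        with pytest.raises(ValueError, match="reference"):
            TrialSet.from_dataframe(df, "s")

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            make_trial_set([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])
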