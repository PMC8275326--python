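import numpy as np
import pytest
from scipy import integrate, stats

from labopt.baselines import (
    BatchBOConfig,
    batch_bo,
    expected_improvement,
    lhs_sample,
    probability_of_improvement,
    random_select,
)
from labopt.objectives import objective_series
from labopt.space import ConfigSpace, ParameterDef, ParameterKind
from labopt.surrogate import GPSurrogate


class TestAcquisitionFormulas:
    @pytest.mark.parametrize("seed", range(5))
    def test_ei_pi_match_numerical_integration(self, seed):
        rng = np.random.default_rng(seed)
        gp = GPSurrogate(dim=1)
        gp.add_observation(rng.uniform(size=1), rng.normal())
        best = float(gp.y.max())
        x = rng.uniform(size=1)
        mean, var = gp.posterior(x)
        sd = np.sqrt(var)

        # integrate upward from the kink at `best` so quad sees a smooth
        # integrand
        ei_ref, _ = integrate.quad(
            lambda t: (t - best) * stats.norm.pdf(t, mean, sd),
            best,
            max(best, mean) + 12 * sd,
        )
        pi_ref = 1.0 - stats.norm.cdf(best, mean, sd)
        assert expected_improvement([mean], [sd], best)[0] == pytest.approx(
            ei_ref, abs=1e-9
        )
        assert probability_of_improvement([mean], [sd], best)[0] == pytest.approx(
            pi_ref, abs=1e-12
        )

    def test_zero_variance_limits(self):
        assert expected_improvement([1.0], [0.0], 0.5)[0] == pytest.approx(0.5)
        assert expected_improvement([0.2], [0.0], 0.5)[0] == 0.0
        assert probability_of_improvement([1.0], [0.0], 0.5)[0] == 1.0
        assert probability_of_improvement([0.2], [0.0], 0.5)[0] == 0.0


@pytest.fixture(scope="module")
def small_problem(request):
    rng = np.random.default_rng(42)
    scaled = rng.uniform(size=(30, 2))
    values = -np.sum((scaled - 0.6) ** 2, axis=1)
    return scaled, values


class TestBatchBO:
    def test_budget_equal_to_initial_batch(self, small_problem):
        scaled, values = small_problem
        cfg = BatchBOConfig(acquisition="ei", batch_size=4, budget=4, seed=0)
        hist = batch_bo(scaled, values, cfg)
        assert len(hist.order) == 4

    @pytest.mark.parametrize("acq", ["ts", "ei", "pi", "ucb"])
    def test_seeded_reproducibility(self, small_problem, acq):
        scaled, values = small_problem
        cfg = BatchBOConfig(acquisition=acq, batch_size=3, budget=12, seed=5)
        h1 = batch_bo(scaled, values, cfg)
        h2 = batch_bo(scaled, values, cfg)
        assert h1.order == h2.order

    def test_no_candidate_repeated(self, small_problem):
        scaled, values = small_problem
        cfg = BatchBOConfig(acquisition="ucb", batch_size=4, budget=20, seed=1)
        hist = batch_bo(scaled, values, cfg)
        assert len(hist.order) == len(set(hist.order))

    def test_best_so_far_monotone(self, small_problem):
        scaled, values = small_problem
        cfg = BatchBOConfig(acquisition="ts", batch_size=4, budget=16, seed=2)
        hist = batch_bo(scaled, values, cfg)
        assert np.all(np.diff(hist.best_so_far) >= 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            BatchBOConfig(acquisition="nope")
        with pytest.raises(ValueError):
            BatchBOConfig(acquisition="ei", batch_size=8, budget=4)

    def test_acquisitions_beat_random_on_smooth_surface(self, bowl_sweep):
        # structural mirror of the success-probability study: over seeded
        # repeats on a smooth 120-row sweep, every model-based acquisition
        # finds the planted optimum more often than uniform random choice
        df, key, space = bowl_sweep
        values = objective_series(df, "height")
        scaled = np.array([space.scale(list(r)) for r in df[space.names].to_numpy()])
        repeats = 15
        rand = np.mean(
            [random_select(len(df), values, 25, s).found_optimum for s in range(200)]
        )
        for acq in ("ts", "ei", "pi", "ucb"):
            succ = np.mean(
                [
                    batch_bo(
                        scaled,
                        values,
                        BatchBOConfig(acquisition=acq, batch_size=4, budget=25, seed=s),
                    ).found_optimum
                    for s in range(repeats)
                ]
            )
            assert succ > rand
            assert succ < 1.0 + 1e-9  # never better than exhaustive search


class TestRandomSelect:
    def test_full_budget_always_finds_optimum(self):
        values = np.arange(10.0)
        hist = random_select(10, values, budget=10, seed=0)
        assert hist.found_optimum

    def test_success_probability_matches_hypergeometric(self):
        # drawing 25 of 120 without replacement hits a unique optimum row
        # with probability exactly 25/120
        values = np.zeros(120)
        values[17] = 1.0
        hits = np.mean(
            [random_select(120, values, 25, seed).found_optimum
             for seed in range(4000)]
        )
        assert hits == pytest.approx(25 / 120, abs=0.02)

    def test_seeded_reproducibility(self):
        values = np.arange(50.0)
        assert (
            random_select(50, values, 20, 7).order
            == random_select(50, values, 20, 7).order
        )

    def test_budget_validation(self):
        with pytest.raises(ValueError):
            random_select(10, np.arange(10.0), budget=11, seed=0)


class TestLHS:
    @pytest.fixture
    def hplc_space(self):
        return ConfigSpace(
            [
                ParameterDef("flow_rate", ParameterKind.CONTINUOUS,
                             bounds=(0.2, 2.0)),
                ParameterDef("injection_volume", ParameterKind.CONTINUOUS,
                             bounds=(1.0, 50.0)),
                ParameterDef("column_temperature", ParameterKind.CONTINUOUS,
                             bounds=(25.0, 45.0)),
                ParameterDef("wavelength", ParameterKind.CONTINUOUS,
                             bounds=(260.0, 285.0)),
                ParameterDef("solvent_ratio", ParameterKind.LEVELS,
                             levels=["65:35", "70:30", "75:25", "80:20"]),
                ParameterDef("gradient", ParameterKind.CATEGORICAL,
                             levels=["non-linear", "constant", "quick linear",
                                     "linear", "slow linear"]),
            ]
        )

    def test_single_sample(self, hplc_space):
        out = lhs_sample(hplc_space, 1, seed=0)
        assert len(out) == 1 and len(out[0]) == 6

    def test_continuous_dimensions_stratified(self, hplc_space):
        n = 18
        out = lhs_sample(hplc_space, n, seed=1)
        lo, hi = 0.2, 2.0
        strata = [int(np.floor((c[0] - lo) / (hi - lo) * n)) for c in out]
        strata = [min(s, n - 1) for s in strata]
        assert sorted(strata) == list(range(n))

    def test_eighteen_samples_within_printed_ranges(self, hplc_space):
        out = lhs_sample(hplc_space, 18, seed=2)
        for cfg in out:
            assert 0.2 <= cfg[0] <= 2.0
            assert 1.0 <= cfg[1] <= 50.0
            assert 25.0 <= cfg[2] <= 45.0
            assert 260.0 <= cfg[3] <= 285.0
            assert cfg[4] in ["65:35", "70:30", "75:25", "80:20"]
            assert cfg[5] in ["non-linear", "constant", "quick linear",
                              "linear", "slow linear"]

    def test_seeded_reproducibility(self, hplc_space):
        assert lhs_sample(hplc_space, 6, 3) == lhs_sample(hplc_space, 6, 3)

    def test_n_validation(self, hplc_space):
        with pytest.raises(ValueError):
            lhs_sample(hplc_space, 0, seed=0)
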