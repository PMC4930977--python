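import numpy as np
import pytest

import matechoice.estimators as est
from matechoice.choice_test import (
    CandidatePool,
    bootstrap_null,
    build_pool,
    exact_two_tailed_p,
    exponential_kernel,
    observed_difference,
    spearman_correlation,
    table_kernel,
    uniform_kernel,
)
from matechoice.genotype_io import (
    DistanceMatrix,
    Individual,
    PopulationRegistry,
    ReproductiveEvent,
    Status,
)


def _registry(distances, year=2000, males=("m1", "m2"), female_terr="T1"):
    terrs = distances.territories
    inds = [
        Individual("f1", "F", year - 5, {year: female_terr}, {year: Status.DOMINANT})
    ]
    for i, m in enumerate(males):
        t = terrs[min(i, len(terrs) - 1)]
        inds.append(
            Individual(m, "M", year - 5, {year: t}, {year: Status.DOMINANT})
        )
    return PopulationRegistry(inds, distances)


def _event(male="m1", pups=("p1",), year=2000, terr="T1"):
    return ReproductiveEvent("f1", year, male, tuple(pups), 0, terr)


class TestKernelsAndPools:
    def test_equal_distance_gives_equal_weights(self):
        d = DistanceMatrix(["T1", "T2", "T3"],
                           np.array([[0, 2, 2], [2, 0, 1], [2, 1, 0]], float))
        reg = _registry(d, males=("m1", "m2"))
        # both males at distance 2 from T1? m1 on T1 (distance 0) -- place both away
        reg.individuals["m1"].territory_by_year[2000] = "T2"
        reg.individuals["m2"].territory_by_year[2000] = "T3"
        pool = build_pool(_event(), reg, min_age=0, kernel=exponential_kernel(0.7))
        assert pool.weights == pytest.approx([0.5, 0.5])

    def test_uniform_kernel_ignores_distance(self):
        d = DistanceMatrix(["T1", "T2"], np.array([[0, 9.0], [9.0, 0]]))
        reg = _registry(d)
        pool = build_pool(_event(), reg, min_age=0, kernel=uniform_kernel)
        assert pool.weights == pytest.approx([0.5, 0.5])

    def test_exponential_kernel_closed_form(self):
        d = DistanceMatrix(["T1", "T2"], np.array([[0, 2.0], [2.0, 0]]))
        reg = _registry(d)  # m1 at distance 0, m2 at distance 2
        pool = build_pool(_event(), reg, min_age=0, kernel=exponential_kernel(0.5))
        w1 = 1.0 / (1.0 + np.exp(-1.0))
        assert dict(zip(pool.males, pool.weights)) == pytest.approx(
            {"m1": w1, "m2": 1 - w1}
        )

    def test_social_male_always_in_pool(self):
        d = DistanceMatrix(["T1"], np.zeros((1, 1)))
        reg = _registry(d, males=("m1",))
        # social male fails the age filter but is demonstrably available
        pool = build_pool(_event(), reg, min_age=30, kernel=uniform_kernel)
        assert pool.males == ("m1",)

    def test_table_kernel_steps(self):
        k = table_kernel([1.0, 3.0], [0.7, 0.3])
        assert k(0.5) == 0.7 and k(2.0) == 0.3 and k(99.0) == 0.3

    def test_min_age_filters(self):
        d = DistanceMatrix(["T1"], np.zeros((1, 1)))
        inds = [
            Individual("f1", "F", 1995, {2000: "T1"}, {2000: Status.DOMINANT}),
            Individual("m1", "M", 1995, {2000: "T1"}, {2000: Status.DOMINANT}),
            Individual("y", "M", 1998, {2000: "T1"}, {2000: Status.SUBORDINATE}),
        ]
        reg = PopulationRegistry(inds, d)
        pool = build_pool(_event(), reg, min_age=3, kernel=uniform_kernel)
        assert pool.males == ("m1",)


class TestObservedDifference:
    def _simple(self, values, social="m1", males=("m1", "m2", "m3")):
        ev = _event(male=social)
        n = len(males)
        pool = CandidatePool(ev, tuple(males), tuple([0.0] * n), np.full(n, 1 / n))
        return [ev], [pool], lambda e, m: values[m]

    def test_zero_when_candidates_equal_social(self):
        events, pools, value = self._simple({"m1": 1.0, "m2": 1.0, "m3": 1.0})
        assert observed_difference(events, pools, value) == pytest.approx(0.0)

    def test_social_one_candidates_zero(self):
        events, pools, value = self._simple({"m1": 1.0, "m2": 0.0, "m3": 0.0})
        assert observed_difference(events, pools, value) == pytest.approx(1.0)

    def test_three_event_hand_computed(self):
        # hand-computed weighted means with renormalised candidate weights
        vals = {"a": 2.0, "b": 1.0, "c": 4.0}
        events, pools = [], []
        for social, w in [("a", (0.5, 0.25, 0.25)), ("b", (0.2, 0.4, 0.4)), ("c", (0.6, 0.2, 0.2))]:
            ev = _event(male=social)
            events.append(ev)
            pools.append(CandidatePool(ev, ("a", "b", "c"), (0.0,) * 3, np.array(w)))
        value = lambda e, m: vals[m]
        # event1 social a: candidates b,c weights (.25,.25)->(.5,.5): mean 2.5, diff -0.5
        # event2 social b: candidates a,c weights (.2,.4)->(1/3,2/3): mean 10/3, diff -7/3
        # event3 social c: candidates a,b weights (.6,.2)->(.75,.25): mean 1.75, diff 2.25
        expected = (-0.5 - 7.0 / 3.0 + 2.25) / 3.0
        assert observed_difference(events, pools, value) == pytest.approx(expected, abs=1e-12)

    def test_undefined_value_drops_event(self):
        vals = {"m1": 1.0, "m2": None, "m3": 0.0}
        events, pools, value = self._simple(vals)
        with pytest.raises(ValueError):
            observed_difference(events, pools, value)


class TestExactTwoTailedP:
    def test_hand_enumeration(self):
        assert exact_two_tailed_p(4.5, [1, 2, 3, 4, 5]) == pytest.approx(0.4)

    def test_observed_at_mean_is_near_one(self):
        rng = np.random.default_rng(0)
        sims = rng.normal(size=1000)
        assert exact_two_tailed_p(sims.mean(), sims) == 1.0

    def test_beyond_all_sims_is_zero(self):
        assert exact_two_tailed_p(100.0, [1, 2, 3]) == 0.0


class TestBootstrapNull:
    def _fixture(self, seed=0, n_events=10, pool=8):
        rng = np.random.default_rng(seed)
        events, pools, vals = [], [], {}
        for e in range(n_events):
            males = tuple(f"m{e}_{k}" for k in range(pool))
            for m in males:
                vals[m] = rng.normal()
            ev = ReproductiveEvent(f"f{e}", 2000, males[0], ("p",), 0, "T1")
            w = rng.random(pool) + 0.1
            events.append(ev)
            pools.append(CandidatePool(ev, males, (0.0,) * pool, w / w.sum()))
        return events, pools, (lambda e, m: vals[m])

    def test_constant_statistic_gives_zero_diffs(self):
        events, pools, _ = self._fixture()
        res = bootstrap_null(events, pools, lambda e, m: 3.14, B=50, seed=1)
        assert res.observed_diff == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.sim_diffs, 0.0, atol=1e-12)

    def test_reproducible_under_fixed_seed(self):
        events, pools, value = self._fixture()
        r1 = bootstrap_null(events, pools, value, B=40, seed=9)
        r2 = bootstrap_null(events, pools, value, B=40, seed=9)
        assert np.array_equal(r1.sim_diffs, r2.sim_diffs)
        assert r1.p_two_tailed == r2.p_two_tailed

    def test_translation_invariance_of_p(self):
        events, pools, value = self._fixture(seed=3)
        r1 = bootstrap_null(events, pools, value, B=200, seed=5)
        r2 = bootstrap_null(events, pools, lambda e, m: value(e, m) + 100.0, B=200, seed=5)
        assert r1.p_two_tailed == r2.p_two_tailed
        assert r1.observed_diff == pytest.approx(r2.observed_diff, abs=1e-9)

    def test_ci95_are_percentiles(self):
        events, pools, value = self._fixture(seed=4)
        res = bootstrap_null(events, pools, value, B=300, seed=6)
        assert res.ci95[0] == pytest.approx(np.percentile(res.sim_diffs, 2.5))
        assert res.ci95[1] == pytest.approx(np.percentile(res.sim_diffs, 97.5))
        assert 0.0 <= res.p_two_tailed <= 1.0

    def test_singleton_pool_contributes_zero_and_flagged(self):
        ev = _event(male="m1")
        pool = CandidatePool(ev, ("m1",), (0.0,), np.array([1.0]))
        res = bootstrap_null([ev], [pool], lambda e, m: 2.0, B=10, seed=0)
        assert res.n_singleton == 1
        assert res.observed_diff == 0.0

    def test_single_candidate_mode_runs(self):
        events, pools, value = self._fixture(seed=8)
        res = bootstrap_null(events, pools, value, B=30, seed=2, mode="single_candidate")
        assert res.sim_diffs.shape == (30,)
        assert res.mode == "single_candidate"

    def test_uniform_kernel_invariant_to_distances(self, small_dataset):
        ds = small_dataset
        gt = ds.genotypes
        het = est.observed_heterozygosity(gt)
        cache = {}

        def value(event, male):
            if male not in cache:
                cache[male] = est.standardized_heterozygosity(male, gt, het).value
            return cache[male]

        reg = ds.registry
        scrambled = PopulationRegistry(
            list(reg.individuals.values()),
            DistanceMatrix(reg.distances.territories, reg.distances.matrix * 7.5),
        )
        pools1 = [build_pool(e, reg, min_age=2, kernel=uniform_kernel) for e in ds.events]
        pools2 = [build_pool(e, scrambled, min_age=2, kernel=uniform_kernel) for e in ds.events]
        r1 = bootstrap_null(ds.events, pools1, value, B=50, seed=3)
        r2 = bootstrap_null(ds.events, pools2, value, B=50, seed=3)
        assert np.array_equal(r1.sim_diffs, r2.sim_diffs)
        assert r1.observed_diff == r2.observed_diff


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(20.0)
        assert spearman_correlation(x, x**3).rho == pytest.approx(1.0)
        assert spearman_correlation(x, -x).rho == pytest.approx(-1.0)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(44)
        hits = 0
        for _ in range(20):
            res = spearman_correlation(rng.normal(size=150), rng.normal(size=150))
            hits += abs(res.rho) < 0.2
        assert hits >= 19

    def test_ci_brackets_rho(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        y = x + rng.normal(size=100)
        res = spearman_correlation(x, y)
        assert res.ci95[0] < res.rho < res.ci95[1]
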