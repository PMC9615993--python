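"""Two-species occupancy likelihood, Gibbs sampler and posterior summaries."""

import itertools

import numpy as np
import pytest

from sympatric import (
    DetectionPair,
    OccupancySpec,
    TwoSpeciesParams,
    compute_sif,
    gibbs_sampler,
    hdi,
    ml_fit,
    rhat,
    simulate_two_species,
    site_likelihood,
    summarize_posterior,
)


def brute_force_likelihood(params: TwoSpeciesParams, histA, histB) -> float:
    """Independent oracle: explicit loop over latent states and occasions."""
    e = params.effective()
    histA = np.asarray(histA, float)
    histB = np.asarray(histB, float)
    total = 0.0
    for zA, zB in itertools.product((0, 1), repeat=2):
        w = (e.psiA if zA else 1 - e.psiA) * (
            (e.psiBA if zB else 1 - e.psiBA) if zA
            else (e.psiBa if zB else 1 - e.psiBa)
        )
        like = 1.0
        for yA, yB in zip(histA, histB):
            if np.isnan(yA):
                continue
            pa = e.rA if (zA and zB) else e.pA
            like *= (pa if yA else 1 - pa) if zA else (0.0 if yA else 1.0)
            if zB:
                if zA:
                    pb = e.rBA if yA else e.rBa
                else:
                    pb = e.pB
                like *= pb if yB else 1 - pb
            else:
                like *= 0.0 if yB else 1.0
        total += w * like
    return total


class TestSiteLikelihood:
    @pytest.mark.parametrize(
        "histA, histB, expected",
        [([0, 0], [0, 0], 0.390625), ([1], [0], 0.1875)],
    )
    def test_half_probability_examples(self, histA, histB, expected):
        p = TwoSpeciesParams(0.5, 0.5, 0.5, 0.5, 0.5)
        assert site_likelihood(p, histA, histB) == pytest.approx(expected, abs=1e-12)

    def test_guaranteed_detection_contradicted(self):
        p = TwoSpeciesParams(1 - 1e-12, 0.5, 0.5, 1 - 1e-12, 0.5)
        assert site_likelihood(p, [0], [0]) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("conditional", [False, True])
    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_matches_enumeration_and_sums_to_one(self, rng, K, conditional):
        """All 2^(2K) paired histories: agreement with the loop oracle to
        1e-12 and unit total probability mass."""
        for _ in range(20):
            kw = {}
            if conditional:
                kw = dict(rA=rng.uniform(0.05, 0.95),
                          rBA=rng.uniform(0.05, 0.95),
                          rBa=rng.uniform(0.05, 0.95))
            p = TwoSpeciesParams(*rng.uniform(0.05, 0.95, 5), **kw)
            total = 0.0
            for histA in itertools.product((0, 1), repeat=K):
                for histB in itertools.product((0, 1), repeat=K):
                    got = site_likelihood(p, histA, histB)
                    assert got == pytest.approx(
                        brute_force_likelihood(p, histA, histB), abs=1e-12
                    )
                    total += got
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_missing_occasions_skipped(self, rng):
        p = TwoSpeciesParams(*rng.uniform(0.1, 0.9, 5))
        with_nan = site_likelihood(p, [1, np.nan], [0, np.nan])
        assert with_nan == pytest.approx(site_likelihood(p, [1], [0]), abs=1e-14)

    def test_mismatched_missing_pattern_rejected(self):
        p = TwoSpeciesParams(0.5, 0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            site_likelihood(p, [1, np.nan], [0, 0])


class TestComputeSif:
    def test_independence_gives_one(self, rng):
        for _ in range(10):
            psiA, psiB = rng.uniform(0.05, 0.95, 2)
            assert compute_sif(psiA, psiB, psiB) == pytest.approx(1.0)

    def test_avoidance_example(self):
        assert compute_sif(0.5, 0.3, 0.6) == pytest.approx(0.6667, abs=1e-4)

    def test_exclusive_subordinate(self):
        assert compute_sif(0.5, 0.4, 1e-300) == pytest.approx(2.0)

    def test_undefined_marginal_rejected(self):
        with pytest.raises(ValueError):
            compute_sif(0.5, 0.0, 0.0)


class TestHdi:
    def test_constant_samples(self):
        assert hdi(np.full(50, 0.2)) == (0.2, 0.2)

    def test_uniform_grid_width(self):
        x = np.arange(1, 1001) / 1000.0
        lo, hi = hdi(x, 0.95)
        assert hi - lo == pytest.approx(0.949, abs=1e-9)

    def test_full_mass_spans_range(self, rng):
        x = rng.normal(size=200)
        assert hdi(x, 1.0) == (x.min(), x.max())

    def test_shorter_than_equal_tailed_on_skewed_sample(self, rng):
        x = rng.gamma(2.0, size=5000)
        lo, hi = hdi(x, 0.95)
        q = np.quantile(x, [0.025, 0.975])
        assert hi - lo <= q[1] - q[0]
        inside = np.mean((x >= lo) & (x <= hi))
        assert inside >= 0.95

    def test_matches_arviz_shortest_interval(self, rng):
        arviz = pytest.importorskip("arviz")
        x = rng.normal(size=2000)
        lo, hi = hdi(x, 0.94)
        ref = arviz.hdi(x, hdi_prob=0.94)
        assert (lo, hi) == pytest.approx(tuple(ref), abs=5e-3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.array([]))


class TestRhat:
    def test_same_distribution_chains_near_one(self, rng):
        chains = rng.normal(size=(4, 2000))
        assert rhat(chains) == pytest.approx(1.0, abs=0.05)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert rhat(chains) > 1.1

    def test_single_or_tiny_chains_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            rhat(np.zeros((2, 2)))


class TestGibbs:
    def test_recovers_generating_parameters(self):
        spec = OccupancySpec(n_sites=200, K=10, missing_fraction=0.1)
        pair, _, _ = simulate_two_species(spec, seed=7)
        res = gibbs_sampler(pair, chains=3, burn_in=1500, iterations=800, seed=7)
        summ = summarize_posterior(res).table
        for name, truth in [("psiA", 0.5), ("psiBA", 0.3), ("psiBa", 0.6),
                            ("pA", 0.4), ("pB", 0.4)]:
            assert abs(summ.loc[name, "mean"] - truth) < 0.1, name
        assert (summ["rhat"] < 1.1).all()

    def test_independent_species_give_sif_near_one(self):
        spec = OccupancySpec(psiBA=0.45, psiBa=0.45, n_sites=300, K=10,
                             missing_fraction=0.0)
        pair, _, _ = simulate_two_species(spec, seed=11)
        res = gibbs_sampler(pair, chains=3, burn_in=1500, iterations=800, seed=11)
        summ = summarize_posterior(res)
        assert abs(summ.table.loc["SIF", "mean"] - 1.0) < 0.1
        assert not summ.hdi_excludes_one

    def test_same_seed_bit_identical(self):
        pair, _, _ = simulate_two_species(OccupancySpec(n_sites=30, K=5), seed=3)
        a = gibbs_sampler(pair, chains=2, burn_in=50, iterations=50, seed=5)
        b = gibbs_sampler(pair, chains=2, burn_in=50, iterations=50, seed=5)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_empty_pair_rejected(self):
        pair = DetectionPair([], np.empty((0, 3)), np.empty((0, 3)))
        with pytest.raises(ValueError, match="empty"):
            gibbs_sampler(pair, chains=2, burn_in=10, iterations=10, seed=0)

    def test_all_missing_rejected(self):
        m = np.full((3, 4), np.nan)
        pair = DetectionPair(["a", "b", "c"], m, m.copy())
        with pytest.raises(ValueError, match="missing"):
            gibbs_sampler(pair, chains=2, burn_in=10, iterations=10, seed=0)

    def test_species_never_detected_warns(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        b = np.zeros((2, 2))
        pair = DetectionPair(["a", "b"], a, b)
        with pytest.warns(UserWarning, match="never detected"):
            gibbs_sampler(pair, chains=2, burn_in=20, iterations=20, seed=0)

    def test_conditional_detection_variant_runs_and_recovers_occupancy(self):
        spec = OccupancySpec(n_sites=200, K=10, missing_fraction=0.0)
        pair, _, _ = simulate_two_species(spec, seed=13)
        res = gibbs_sampler(pair, chains=2, burn_in=1000, iterations=600,
                            seed=13, conditional_detection=True)
        summ = summarize_posterior(res).table
        # generating process has detection independent of the companion,
        # so r parameters should agree with their p counterparts
        assert abs(summ.loc["psiA", "mean"] - 0.5) < 0.12
        assert abs(summ.loc["rA", "mean"] - summ.loc["pA", "mean"]) < 0.15


class TestMlFit:
    def test_consistency_and_agreement_with_gibbs(self):
        spec = OccupancySpec(n_sites=1000, K=10, missing_fraction=0.05)
        pair, _, _ = simulate_two_species(spec, seed=21)
        params, converged = ml_fit(pair)
        assert converged
        truth = dict(psiA=0.5, psiBA=0.3, psiBa=0.6, pA=0.4, pB=0.4)
        for name, v in truth.items():
            assert abs(getattr(params, name) - v) < 0.05, name
        res = gibbs_sampler(pair, chains=2, burn_in=1000, iterations=600, seed=21)
        summ = summarize_posterior(res).table
        for name in truth:
            assert abs(summ.loc[name, "mean"] - getattr(params, name)) < 0.05, name

    def test_subordinate_never_present_flagged(self):
        rng = np.random.default_rng(5)
        a = rng.binomial(1, 0.4, (100, 8)).astype(float)
        b = np.zeros((100, 8))
        pair = DetectionPair([f"s{i}" for i in range(100)], a, b)
        with pytest.warns(UserWarning):
            params, converged = ml_fit(pair)
        assert not converged
        assert params.psiBA < 0.05 or params.psiBa < 0.05
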