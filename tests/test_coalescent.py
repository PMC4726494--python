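"""Sequential-importance-sampling coalescent: likelihoods, θ, TMRCA.

Validation strategy: closed forms where they exist (n=2 competing
exponentials), an exact dynamic-programming solution of the sample-
probability recursion for small configurations, and a forward
rejection sampler that is fully independent of the backward machinery.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cobitis.coalescent import (
    HaplotypeSample,
    check_infinite_sites,
    ewens_ml_theta,
    ml_theta_profile,
    rooted_compatible,
    sis_loglik,
    tmrca_posterior,
    watterson_theta,
    weighted_quantile,
)
from cobitis.simulate import simulate_infinite_sites_sample

from .oracles import (
    canonical_configuration,
    ewens_theta_bisect,
    exact_sample_probability,
    state_of_sample,
)


def pair_sample(n_sites: int = 0) -> HaplotypeSample:
    """n=2 sample: one lineage carries ``n_sites`` private mutations."""
    if n_sites == 0:
        return HaplotypeSample(np.zeros((0, 1), dtype=np.int8), np.array([2]))
    mat = np.zeros((n_sites, 2), dtype=np.int8)
    mat[:, 0] = 1
    return HaplotypeSample(mat, np.array([1, 1]))


class TestSampleContainer:
    def test_from_sequences_collapses_duplicates(self):
        s = HaplotypeSample.from_sequences([[1, 0], [1, 0], [0, 1]])
        assert s.n == 3 and s.n_distinct == 2 and s.n_sites == 2

    def test_invariant_column_rejected(self):
        with pytest.raises(ValueError, match="invariant"):
            HaplotypeSample(np.ones((1, 2), dtype=np.int8), np.array([1, 1]))

    def test_from_fasta_biallelic_reduction(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGTA\n>b\nACGAA\n>c\nACCAA\n")
        s = HaplotypeSample.from_fasta(p)
        assert s.n == 3 and s.n_sites == 2


class TestInfiniteSites:
    def test_four_gamete_violation_reported(self):
        mat = np.array([[0, 0, 1, 1], [0, 1, 0, 1]], dtype=np.int8)
        ok, conflicts = check_infinite_sites(
            HaplotypeSample(mat, np.array([1, 1, 1, 1])))
        assert not ok and conflicts == [(0, 1)]

    def test_single_site_always_passes(self):
        ok, conflicts = check_infinite_sites(pair_sample(1))
        assert ok and conflicts == []

    def test_simulated_samples_always_compatible(self):
        for seed in range(25):
            sample, _ = simulate_infinite_sites_sample(8, 2.0, seed=seed)
            ok, _ = check_infinite_sites(sample)
            assert ok and rooted_compatible(sample)


class TestEwens:
    def test_monomorphic_gives_zero(self):
        assert ewens_ml_theta(10, 1).theta == 0.0

    def test_all_distinct_unbounded(self):
        assert ewens_ml_theta(5, 5).unbounded

    @pytest.mark.parametrize("n,k", [(10, 5), (30, 12), (7, 3)])
    def test_matches_bisection_oracle(self, n, k):
        assert ewens_ml_theta(n, k).theta == pytest.approx(
            ewens_theta_bisect(n, k), abs=1e-6)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            ewens_ml_theta(4, 5)


class TestSisClosedForms:
    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0])
    def test_pair_no_mutation_likelihood(self, theta):
        """P(no mutation before coalescence) = 1/(1+θ), exact for every particle."""
        r = sis_loglik(pair_sample(0), theta, n_particles=500, seed=1)
        assert math.exp(r.loglik) == pytest.approx(1.0 / (1.0 + theta), rel=1e-12)

    def test_theta_zero_with_sites_is_impossible(self):
        r = sis_loglik(pair_sample(1), 0.0, n_particles=10, seed=0)
        assert r.loglik == -math.inf

    def test_pair_singleton_closed_form(self):
        # exactly one mutation on a marked lineage: θ/(2(1+θ)²)
        theta = 1.0
        r = sis_loglik(pair_sample(1), theta, n_particles=5000, seed=2)
        expect = theta / (2.0 * (1.0 + theta) ** 2)
        assert math.exp(r.loglik) == pytest.approx(expect, rel=1e-9)

    @pytest.mark.parametrize("theta", [0.5, 2.0])
    def test_pair_tmrca_is_competing_exponential(self, theta):
        """Conditional on no mutations, T ~ Exp(1+θ): mean 1/(1+θ)."""
        t = tmrca_posterior(pair_sample(0), theta, n_particles=40_000, seed=3)
        mean = 1.0 / (1.0 + theta)
        se = mean / math.sqrt(40_000)
        assert t.mean == pytest.approx(mean, abs=4 * se)
        assert t.ci_low <= t.mean <= t.ci_high

    def test_pair_theta_to_zero_mean_one(self):
        t = tmrca_posterior(pair_sample(0), 1e-9, n_particles=20_000, seed=4)
        assert t.mean == pytest.approx(1.0, abs=0.03)


def small_configurations():
    """All rooted-compatible configurations with n<=4, <=2 segregating sites."""
    cases = []
    z = np.zeros((0, 1), dtype=np.int8)
    for n in (2, 3, 4):
        cases.append(HaplotypeSample(z, np.array([n])))
    # one site with multiplicity splits
    for carriers, others in [(1, 1), (1, 2), (2, 1), (1, 3), (2, 2), (3, 1)]:
        mat = np.array([[1, 0]], dtype=np.int8)
        cases.append(HaplotypeSample(mat, np.array([carriers, others])))
    # two sites: nested, disjoint, doubled
    two = [
        (np.array([[1, 0], [1, 0]], dtype=np.int8), [1, 1]),       # both on one hap
        (np.array([[1, 0], [1, 0]], dtype=np.int8), [1, 3]),
        (np.array([[1, 0, 0], [0, 1, 0]], dtype=np.int8), [1, 1, 1]),  # disjoint
        (np.array([[1, 0, 0], [0, 1, 0]], dtype=np.int8), [1, 1, 2]),
        (np.array([[1, 1, 0], [0, 1, 0]], dtype=np.int8), [1, 1, 1]),  # nested
        (np.array([[1, 1, 0], [0, 1, 0]], dtype=np.int8), [1, 1, 2]),
    ]
    for mat, mult in two:
        cases.append(HaplotypeSample(mat, np.array(mult)))
    return cases


class TestSisAgainstEnumeration:
    @pytest.mark.parametrize("theta", [0.7, 1.8])
    def test_all_small_configurations(self, theta):
        """SIS estimate within 3 MC standard errors of the exact recursion
        solved by exhaustive dynamic programming."""
        for sample in small_configurations():
            exact = exact_sample_probability(state_of_sample(sample), theta)
            r = sis_loglik(sample, theta, n_particles=6000, seed=11)
            est = math.exp(r.loglik)
            se = max(r.mc_se * est, 1e-15)
            assert abs(est - exact) <= max(3 * se, 1e-12), \
                f"n={sample.n} S={sample.n_sites}: {est} vs exact {exact}"


class TestRejectionOracle:
    def test_tmrca_matches_rejection_sampler(self):
        """n=4, one doubleton site: conditional TMRCA from forward rejection
        sampling agrees with the weighted SIS posterior within MC error."""
        target = HaplotypeSample(np.array([[1, 0]], dtype=np.int8), np.array([2, 2]))
        key = canonical_configuration(target.expand())
        theta = 1.0
        hits = []
        for seed in range(40_000):
            s, truth = simulate_infinite_sites_sample(4, theta, seed=seed)
            if s.n_sites == 1 and canonical_configuration(s.expand()) == key:
                hits.append(truth.latent["tmrca"])
        assert len(hits) > 500
        rej_mean = float(np.mean(hits))
        rej_se = float(np.std(hits) / math.sqrt(len(hits)))
        t = tmrca_posterior(target, theta, n_particles=30_000, seed=5)
        assert t.mean == pytest.approx(rej_mean, abs=4 * rej_se + 0.02)

    def test_likelihood_matches_rejection_probability(self):
        """Unlabeled-configuration probability = (n!/Πn_k!) × ordered-sample
        probability from the recursion."""
        target = HaplotypeSample(np.array([[1, 0]], dtype=np.int8), np.array([1, 2]))
        key = canonical_configuration(target.expand())
        theta = 0.5
        N = 40_000
        hits = sum(
            1 for seed in range(N)
            if simulate_infinite_sites_sample(3, theta, seed=seed)[0].n_sites == 1
            and canonical_configuration(
                simulate_infinite_sites_sample(3, theta, seed=seed)[0].expand()) == key)
        p_unlabeled = hits / N
        se = math.sqrt(p_unlabeled * (1 - p_unlabeled) / N)
        p_ordered = exact_sample_probability(state_of_sample(target), theta)
        assert 3 * p_ordered == pytest.approx(p_unlabeled, abs=4 * se)


class TestThetaProfile:
    def test_monomorphic_hits_lower_bound(self):
        s = HaplotypeSample(np.zeros((0, 1), dtype=np.int8), np.array([10]))
        est = ml_theta_profile(s, theta_grid=[0.01, 0.1, 1.0], n_particles=500, seed=0)
        assert est.theta_hat == pytest.approx(0.01)

    def test_recovery_and_support_interval(self):
        """Simulated at θ=1.156, n=30: the 2-log-unit support interval of the
        profile covers the truth in most replicates."""
        cover = 0
        for rep in range(6):
            sample, _ = simulate_infinite_sites_sample(30, 1.156, seed=500 + rep)
            est = ml_theta_profile(sample, n_particles=3000, seed=600 + rep)
            if est.support2_low <= 1.156 <= est.support2_high:
                cover += 1
        assert cover >= 4

    def test_sis_and_ewens_agree_on_simulated_data(self):
        """Two estimators of θ from different sufficient statistics stay
        within a factor consistent with their sampling noise."""
        ratios = []
        for rep in range(5):
            sample, _ = simulate_infinite_sites_sample(25, 2.0, seed=700 + rep)
            est = ml_theta_profile(sample, n_particles=2000, seed=800 + rep)
            ew = ewens_ml_theta(sample.n, sample.n_distinct)
            if not ew.unbounded and ew.theta > 0:
                ratios.append(est.theta_hat / ew.theta)
        assert ratios and 0.3 < np.median(ratios) < 3.0

    def test_common_random_numbers_smooth_profile(self):
        sample, _ = simulate_infinite_sites_sample(12, 1.0, seed=42)
        est = ml_theta_profile(sample, n_particles=2000, seed=1)
        # re-weighted curve from shared histories: finite everywhere, unimodal-ish
        assert np.all(np.isfinite(est.loglik))
        assert est.grid[0] < est.theta_hat < est.grid[-1] or sample.n_sites == 0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ml_theta_profile(pair_sample(0), theta_grid=[], n_particles=10)


class TestInvariants:
    def test_simulator_mean_tmrca(self):
        """E[TMRCA(n)] = 2(1-1/n) in N_f-generation units."""
        for n in (2, 6):
            tm = [simulate_infinite_sites_sample(n, 0.0, seed=s)[1].latent["tmrca"]
                  for s in range(3000)]
            expect = 2.0 * (1.0 - 1.0 / n)
            se = np.std(tm) / math.sqrt(len(tm))
            assert np.mean(tm) == pytest.approx(expect, abs=3.5 * se)

    def test_simulator_mean_segregating_sites_pair(self):
        theta = 1.5
        ss = [simulate_infinite_sites_sample(2, theta, seed=s)[1].latent["n_segregating"]
              for s in range(4000)]
        se = np.std(ss) / math.sqrt(len(ss))
        assert np.mean(ss) == pytest.approx(theta, abs=3.5 * se)

    def test_loglik_invariant_to_column_order(self):
        mat = np.array([[1, 1, 0], [0, 1, 0]], dtype=np.int8)
        s1 = HaplotypeSample(mat, np.array([1, 1, 2]))
        s2 = HaplotypeSample(mat[:, [2, 0, 1]], np.array([2, 1, 1]))
        r1 = sis_loglik(s1, 1.0, 4000, seed=9)
        r2 = sis_loglik(s2, 1.0, 4000, seed=9)
        assert r1.loglik == pytest.approx(r2.loglik, abs=3 * (r1.mc_se + r2.mc_se))

    def test_particle_doubling_shrinks_error(self):
        sample, _ = simulate_infinite_sites_sample(10, 1.0, seed=13)
        r1 = sis_loglik(sample, 1.0, 2000, seed=1)
        r2 = sis_loglik(sample, 1.0, 8000, seed=1)
        assert r2.mc_se < r1.mc_se
        assert r1.loglik == pytest.approx(r2.loglik, abs=3.5 * (r1.mc_se + r2.mc_se))

    def test_ci_brackets_mean(self):
        for seed in range(5):
            sample, _ = simulate_infinite_sites_sample(12, 1.5, seed=seed)
            t = tmrca_posterior(sample, watterson_theta(sample) or 1.0,
                                n_particles=2000, seed=seed)
            assert t.ci_low <= t.mean <= t.ci_high


class TestWeightedQuantile:
    def test_uniform_weights_match_numpy(self, rng):
        x = rng.normal(size=501)
        w = np.ones_like(x)
        assert weighted_quantile(x, w, 0.5) == pytest.approx(np.median(x), abs=1e-9)

    @given(st.lists(st.floats(0.1, 10.0), min_size=3, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_quantiles_are_monotone(self, ws):
        x = np.arange(len(ws), dtype=float)
        w = np.array(ws)
        q25 = weighted_quantile(x, w, 0.25)
        q75 = weighted_quantile(x, w, 0.75)
        assert q25 <= q75


class TestMsprimeCrossCheck:
    def test_segregating_sites_distribution_matches_msprime(self):
        """Independent coalescent simulator as oracle: S distributions agree
        for n=5, θ=2 (mutation rate θ/2 per lineage per coalescent unit)."""
        msprime = pytest.importorskip("msprime")
        theta = 2.0
        n = 5
        ours = [simulate_infinite_sites_sample(n, theta, seed=s)[1].latent["n_segregating"]
                for s in range(3000)]
        # ploidy=1 with population_size=1 puts msprime time in units where a
        # pair coalesces at rate 1; mutation rate theta/2 over a unit-length
        # continuous genome reproduces the infinite-sites scaling
        reps = msprime.sim_ancestry(
            samples=[msprime.SampleSet(n, ploidy=1)], ploidy=1, population_size=1.0,
            num_replicates=3000, random_seed=99)
        other = []
        for i, ts in enumerate(reps):
            mts = msprime.sim_mutations(ts, rate=theta / 2.0, random_seed=1000 + i,
                                        discrete_genome=False)
            other.append(mts.num_sites)
        m1, m2 = np.mean(ours), np.mean(other)
        se = math.sqrt(np.var(ours) / len(ours) + np.var(other) / len(other))
        assert m1 == pytest.approx(m2, abs=3.5 * se)
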