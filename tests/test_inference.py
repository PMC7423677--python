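"""Likelihood, genealogy density, ESS, and MCMC structural checks.

The heavier distributional validations of the sampler (prior recovery,
Geweke-style joint check, parameter recovery) live in the acceptance
suite; here we pin down exact values, error handling, determinism, and the
equivalence between the compiled engine and the pure-Python reference
implementations.
"""

import math

import numpy as np
import pytest

from mscmig.coalsim import Genealogy, SampleConfig, simulate_genealogy
from mscmig.demography import (DemographicModel, MigrationBand, ModelArrays,
                               PopulationTree)
from mscmig.inference import (McmcSettings, PriorSpec,
                              coalescent_migration_log_density, ess,
                              jc69_log_likelihood, run_mcmc)
from mscmig.seqevolve import LocusAlignment, evolve_jc69


def _two_tip_genealogy(model, t, pops=(0, 0, 0)):
    arr = model.as_arrays()
    return Genealogy(2, [2, 2, -1], [-1, -1, 0], [-1, -1, 1],
                     [0.0, 0.0, t], list(pops), [[], [], []],
                     ["X_0", "X_1"], arr)


class TestJC69Likelihood:
    def test_single_leaf_uniform_root(self, single_pop_model):
        arr = single_pop_model.as_arrays()
        g = Genealogy(1, [-1], [-1], [-1], [0.0], [0], [[]], ["X_0"], arr)
        L = 37
        aln = LocusAlignment("l", ["X_0"], ["A" * L])
        assert jc69_log_likelihood(aln, g) == pytest.approx(
            L * math.log(0.25), rel=1e-12)

    def test_two_leaf_closed_form(self, single_pop_model):
        t_total = 0.02
        g = _two_tip_genealogy(single_pop_model, t_total / 2)
        aln = LocusAlignment("l", ["X_0", "X_1"],
                             ["ACGTACGTAC", "ACGTTCGAAC"])  # 2 mismatches
        e = math.exp(-4 * t_total / 3)
        p_same, p_diff = 0.25 + 0.75 * e, 0.25 - 0.25 * e
        closed = 8 * math.log(0.25 * p_same) + 2 * math.log(0.25 * p_diff)
        assert jc69_log_likelihood(aln, g) == pytest.approx(closed,
                                                            abs=1e-10)

    def test_n_columns_marginalised(self, single_pop_model):
        g = _two_tip_genealogy(single_pop_model, 0.01)
        with_n = LocusAlignment("l", ["X_0", "X_1"], ["ACGNN", "ACGTN"])
        without = LocusAlignment("l", ["X_0", "X_1"], ["ACG", "ACG"])
        # a column that is N in every row contributes exactly 0; a column
        # N in one row marginalises to the single-sequence factor 1/4
        assert jc69_log_likelihood(with_n, g) == pytest.approx(
            jc69_log_likelihood(without, g) + math.log(0.25), rel=1e-12)

    def test_sample_mismatch_raises(self, single_pop_model):
        g = _two_tip_genealogy(single_pop_model, 0.01)
        aln = LocusAlignment("l", ["X_0", "Y_9"], ["AC", "AC"])
        with pytest.raises(ValueError):
            jc69_log_likelihood(aln, g)


class TestCoalescentDensity:
    def test_two_lineage_closed_form(self, single_pop_model):
        theta = 0.001
        for t in (1e-5, 3e-4, 2e-3):
            g = _two_tip_genealogy(single_pop_model, t)
            expected = math.log(2 / theta) - (2 / theta) * t
            assert coalescent_migration_log_density(
                g, single_pop_model) == pytest.approx(expected, rel=1e-12)

    def test_event_on_zero_rate_band_is_impossible(self):
        tree = PopulationTree({"A": "root", "B": "root"}, {"root": 0.001},
                              {"A": 0.001, "B": 0.001, "root": 0.002})
        model = DemographicModel(tree, [MigrationBand("A", "B", 0.0)])
        arr = model.as_arrays()
        # one A and one B lineage; the B lineage jumps to A at t=5e-4
        g = Genealogy(2, [2, 2, -1], [-1, -1, 0], [-1, -1, 1],
                      [0.0, 0.0, 8e-4], [0, 1, 0],
                      [[], [(5e-4, 0)], []], ["A_0", "B_0"], arr)
        assert coalescent_migration_log_density(g, model) == -math.inf

    def test_inconsistent_residence_is_flagged_not_raised(self,
                                                          two_pop_model):
        arr = two_pop_model.as_arrays()
        # coalescence in population A at a time when the lineages sit in
        # different populations
        g = Genealogy(2, [2, 2, -1], [-1, -1, 0], [-1, -1, 1],
                      [0.0, 0.0, 5e-4], [0, 1, 0], [[], [], []],
                      ["A_0", "B_0"], arr)
        assert coalescent_migration_log_density(g, two_pop_model) \
            == -math.inf

    def test_matches_simulator_distribution(self, two_pop_band_model):
        """Simulated first-event waiting times follow the density's rates.

        With one lineage in A and one in B (band A->B, M=200), the waiting
        time to the B lineage's first backward jump is Exp(200) truncated
        at the split; the density assigns exactly this law.
        """
        from scipy import stats
        rng = np.random.default_rng(21)
        cfg = SampleConfig({"A": 1, "B": 1})
        jumps = []
        for _ in range(3000):
            g = simulate_genealogy(two_pop_band_model, cfg, rng)
            if g.events[1]:
                jumps.append(g.events[1][0][0])
        jumps = np.array(jumps)
        trunc = stats.truncexpon(b=200 * 0.001, scale=1 / 200)
        assert stats.kstest(jumps[jumps < 0.001], trunc.cdf).pvalue > 0.01


class TestEngineMatchesOracle:
    def test_final_state_densities_agree(self, two_pop_band_model):
        """Engine-cached likelihood/density equal the Python reference.

        Runs a short chain on data with an active migration band, rebuilds
        every final genealogy as a Python object, and checks both cached
        quantities against the pure-Python implementations.
        """
        rng = np.random.default_rng(5)
        cfg = SampleConfig({"A": 2, "B": 2})
        loci = [evolve_jc69(simulate_genealogy(two_pop_band_model, cfg,
                                               rng), 300, rng, name=f"l{k}")
                for k in range(6)]
        t = run_mcmc(loci, two_pop_band_model, PriorSpec(),
                     McmcSettings(iterations=400, burn_in=100,
                                  sample_every=5, seed=11))
        st = t.final_state
        fa = ModelArrays(st["names"], st["pop_parent"], st["tau"],
                         st["theta"], st["pop_c1"], st["pop_c2"],
                         st["band_src"], st["band_tgt"], st["bM"])
        for l, aln in enumerate(loci):
            events = [[(st["evt"][l, i, k], int(st["evb"][l, i, k]))
                       for k in range(st["nev"][l, i])]
                      for i in range(st["par"].shape[1])]
            g = Genealogy(4, st["par"][l], st["ch1"][l], st["ch2"][l],
                          st["tms"][l], st["npo"][l], events,
                          st["tip_names"], fa)
            assert coalescent_migration_log_density(g, fa) == pytest.approx(
                st["cd"][l], abs=1e-8)
            assert jc69_log_likelihood(aln, g) == pytest.approx(
                st["ll"][l], abs=1e-8)


class TestRunMcmc:
    def test_deterministic_given_seed(self, two_pop_model, rng):
        cfg = SampleConfig({"A": 2, "B": 2})
        loci = [evolve_jc69(simulate_genealogy(two_pop_model, cfg, rng),
                            200, rng, name=f"l{k}") for k in range(4)]
        s = McmcSettings(iterations=300, burn_in=50, sample_every=5, seed=7)
        t1 = run_mcmc(loci, two_pop_model, PriorSpec(), s)
        t2 = run_mcmc(loci, two_pop_model, PriorSpec(), s)
        assert t1.samples.equals(t2.samples)

    def test_finite_log_posterior_throughout(self, two_pop_model, rng):
        cfg = SampleConfig({"A": 2, "B": 2})
        loci = [evolve_jc69(simulate_genealogy(two_pop_model, cfg, rng),
                            200, rng, name=f"l{k}") for k in range(4)]
        t = run_mcmc(loci, two_pop_model, PriorSpec(),
                     McmcSettings(iterations=400, burn_in=100,
                                  sample_every=2, seed=3))
        assert np.isfinite(t.column("logL")).all()
        for col in t.samples.columns:
            assert np.isfinite(t.column(col)).all()

    def test_acceptance_rates_in_open_interval(self, two_pop_model, rng):
        cfg = SampleConfig({"A": 2, "B": 2})
        loci = [evolve_jc69(simulate_genealogy(two_pop_model, cfg, rng),
                            200, rng, name=f"l{k}") for k in range(4)]
        t = run_mcmc(loci, two_pop_model, PriorSpec(),
                     McmcSettings(iterations=500, burn_in=100,
                                  sample_every=5, seed=3))
        for move in ("node_slide", "regraft", "theta", "tau"):
            assert 0.0 < t.acceptance[move] < 1.0

    def test_requires_loci(self, two_pop_model):
        with pytest.raises(ValueError):
            run_mcmc([], two_pop_model)

    def test_resume_continues_chain(self, two_pop_model, rng):
        cfg = SampleConfig({"A": 2, "B": 2})
        loci = [evolve_jc69(simulate_genealogy(two_pop_model, cfg, rng),
                            200, rng, name=f"l{k}") for k in range(3)]
        t1 = run_mcmc(loci, two_pop_model, PriorSpec(),
                      McmcSettings(iterations=100, burn_in=0,
                                   sample_every=100, seed=5))
        t2 = run_mcmc(loci, two_pop_model, PriorSpec(),
                      McmcSettings(iterations=100, burn_in=0,
                                   sample_every=100, seed=6),
                      resume_from=t1.final_state)
        assert np.isfinite(t2.column("logL")).all()


class TestEss:
    def test_iid_series(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        assert ess(x) == pytest.approx(10_000, rel=0.15)

    def test_ar1_series(self):
        rho = 0.9
        rng = np.random.default_rng(1)
        n = 40_000
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + math.sqrt(1 - rho ** 2) * rng.normal()
        expected = n * (1 - rho) / (1 + rho)
        assert ess(x) == pytest.approx(expected, rel=0.25)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ess(np.ones(5))

    def test_constant_series_warns(self):
        with pytest.warns(UserWarning):
            assert ess(np.ones(50)) == 50
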