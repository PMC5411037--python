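"""Scenario priors, the divergence simulator and its summary statistics."""

import numpy as np
import pytest
from scipy.stats import kstest, uniform

from bathypop.coalescent_sim import (
    SUMMARY_NAMES,
    ParameterDraw,
    ScenarioSpec,
    default_priors,
    draw_prior_parameters,
    generations_to_years,
    simulate_scenario,
    summary_statistics,
)
from bathypop.differentiation import fst_weir_cockerham
from bathypop.sim_engine import ALLELE_HI, ALLELE_LO


def _fixed_draw(**kw):
    base = dict(
        scenario=1,
        N_ATL=10_000.0,
        N_MED=10_000.0,
        Nb_ATL=None,
        Nb_MED=None,
        t=2_000.0,
        t1=None,
        N_anc=10_000.0,
        mu_msat_mean=1e-4,
        mu_msat_locus=np.full(9, 1e-4),
        mu_mtdna=2e-8,
    )
    base.update(kw)
    return ParameterDraw(**base)


class TestPriors:
    def test_draws_respect_bounds_and_ordering(self):
        spec = ScenarioSpec(4)
        rng = np.random.default_rng(0)
        pri = default_priors()
        for _ in range(2000):
            d = draw_prior_parameters(spec, rng=rng)
            assert pri["N_ATL"][0] <= d.N_ATL <= pri["N_ATL"][1]
            assert pri["N_MED"][0] <= d.N_MED <= pri["N_MED"][1]
            assert pri["t"][0] <= d.t <= pri["t"][1]
            assert d.t1 < d.t
            assert pri["Nb_ATL"][0] <= d.Nb_ATL <= pri["Nb_ATL"][1]
            assert (d.mu_msat_locus >= pri["mu_msat"][0]).all()
            assert (d.mu_msat_locus <= pri["mu_msat"][1]).all()

    def test_scenario_topologies(self):
        rng = np.random.default_rng(1)
        d1 = draw_prior_parameters(ScenarioSpec(1), rng=rng)
        assert d1.Nb_ATL is None and d1.Nb_MED is None and d1.t1 is None
        d2 = draw_prior_parameters(ScenarioSpec(2), rng=rng)
        assert d2.Nb_ATL is None and d2.Nb_MED is not None
        d3 = draw_prior_parameters(ScenarioSpec(3), rng=rng)
        assert d3.Nb_ATL is not None and d3.Nb_MED is None

    def test_seeded_repeatability(self):
        spec = ScenarioSpec(4)
        a = draw_prior_parameters(spec, seed=42)
        b = draw_prior_parameters(spec, seed=42)
        assert a.as_dict() == b.as_dict()

    def test_t_marginal_is_uniform(self):
        spec = ScenarioSpec(1)
        rng = np.random.default_rng(2)
        ts = [draw_prior_parameters(spec, rng=rng).t for _ in range(1500)]
        lo, hi = default_priors()["t"]
        stat = kstest(ts, uniform(loc=lo, scale=hi - lo).cdf)
        assert stat.pvalue > 0.01


class TestSimulator:
    def test_pairwise_mtdna_diversity_matches_coalescent_expectation(self):
        # haploid effective size N/4: E[pairwise diffs] = 2*(N/4)*mu*L
        draw = _fixed_draw(t=1.0, N_anc=40_000.0, N_ATL=40_000.0, N_MED=40_000.0,
                           mu_mtdna=5e-7)
        rng = np.random.default_rng(3)
        L = 500
        diffs = []
        for _ in range(400):
            s = simulate_scenario(draw, 1, 1, n_loci=1, seq_len=L, rng=rng)
            a, b = s.sequences.sequences
            diffs.append(np.sum(a != b))
        expected = 2 * (40_000 / 4) * 5e-7 * L  # = 5
        assert np.mean(diffs) == pytest.approx(expected, rel=0.1)

    def test_allele_size_variance_grows_with_divergence_time(self):
        # two isolated demes: Var(size difference) ~ mu * 2t for t >> N
        t, mu = 5_000.0, 1e-3
        draw = _fixed_draw(
            N_ATL=50.0, N_MED=50.0, N_anc=50.0, t=t,
            mu_msat_locus=np.full(1, mu), mu_msat_mean=mu, mu_mtdna=0.0,
        )
        rng = np.random.default_rng(4)
        sq = []
        for _ in range(300):
            s = simulate_scenario(draw, 1, 1, n_loci=1, seq_len=10, rng=rng)
            a = s.genotypes.calls[0, 0, 0]
            b = s.genotypes.calls[1, 0, 0]
            sq.append(float(a - b) ** 2)
        assert np.mean(sq) == pytest.approx(2 * mu * t, rel=0.2)

    def test_long_isolation_yields_reciprocal_monophyly(self):
        draw = _fixed_draw(
            scenario=4, N_ATL=200.0, N_MED=200.0, Nb_ATL=200.0, Nb_MED=200.0,
            N_anc=200.0, t=60_000.0, t1=100.0, mu_mtdna=5e-6,
        )
        rng = np.random.default_rng(5)
        shared = 0
        for _ in range(40):
            s = simulate_scenario(draw, 8, 8, n_loci=1, seq_len=300, rng=rng)
            seq = s.sequences
            atl = {x for x, lab in zip(seq.as_strings(), seq.localities) if lab == "ATL"}
            med = {x for x, lab in zip(seq.as_strings(), seq.localities) if lab == "MED"}
            shared += bool(atl & med)
        assert shared <= 2  # >95% of replicates share no haplotypes

    def test_allele_codes_within_bounds(self):
        draw = _fixed_draw(mu_msat_locus=np.full(3, 5e-3), mu_msat_mean=5e-3)
        s = simulate_scenario(draw, 20, 20, n_loci=3, seq_len=50, seed=6)
        assert s.genotypes.calls.min() >= ALLELE_LO
        assert s.genotypes.calls.max() <= ALLELE_HI

    def test_sample_sizes_respected(self):
        draw = _fixed_draw()
        s = simulate_scenario(draw, 7, 5, n_loci=2, seq_len=100, seed=7)
        assert s.genotypes.localities.count("ATL") == 7
        assert s.genotypes.localities.count("MED") == 5
        assert s.sequences.localities.count("ATL") == 7


class TestSummaryStatistics:
    def test_vector_length_and_order_fixed(self):
        draw = _fixed_draw()
        s = simulate_scenario(draw, 10, 10, n_loci=4, seq_len=200, seed=8)
        v = summary_statistics(s)
        assert v.shape == (len(SUMMARY_NAMES),)
        assert SUMMARY_NAMES.index("FST") == 14

    def test_monomorphic_sample_uses_sentinels_without_crashing(self):
        draw = _fixed_draw(mu_msat_locus=np.zeros(2), mu_msat_mean=1e-9, mu_mtdna=0.0)
        s = simulate_scenario(draw, 6, 6, n_loci=2, seq_len=100, seed=9)
        v = summary_statistics(s)
        names = dict(zip(SUMMARY_NAMES, v))
        assert names["A_ATL"] == 1.0
        assert names["HE_ATL"] == 0.0
        assert names["D_ATL"] == -999.0  # undefined, masked

    def test_fst_component_consistent_with_differentiation_module(self):
        draw = _fixed_draw(t=20_000.0, N_ATL=2_000.0, N_MED=2_000.0, N_anc=2_000.0)
        s = simulate_scenario(draw, 15, 15, n_loci=5, seq_len=100, seed=10)
        v = dict(zip(SUMMARY_NAMES, summary_statistics(s)))
        direct = float(fst_weir_cockerham(s.genotypes)["multilocus"])
        assert v["FST"] == pytest.approx(direct)

    def test_exchangeability_of_individual_labels(self):
        draw = _fixed_draw()
        s = simulate_scenario(draw, 12, 12, n_loci=3, seq_len=150, seed=11)
        v1 = summary_statistics(s)
        rng = np.random.default_rng(0)
        # shuffle individuals within each population
        for ds in (s.genotypes,):
            atl = [i for i, p in enumerate(ds.localities) if p == "ATL"]
            med = [i for i, p in enumerate(ds.localities) if p == "MED"]
            order = list(rng.permutation(atl)) + list(rng.permutation(med))
            ds.calls = ds.calls[order]
        v2 = summary_statistics(s)
        np.testing.assert_allclose(v1, v2)

    def test_scenario1_nested_in_scenario4(self):
        """With Nb = N, scenario 4 is distributionally scenario 1 (KS check)."""
        rng = np.random.default_rng(12)
        he1, he4 = [], []
        for _ in range(250):
            d1 = _fixed_draw(N_ATL=3_000.0, N_MED=3_000.0, N_anc=3_000.0, t=3_000.0,
                             mu_msat_locus=np.full(2, 2e-4), mu_msat_mean=2e-4)
            s = simulate_scenario(d1, 8, 8, n_loci=2, seq_len=60, rng=rng)
            he1.append(summary_statistics(s)[2])
            d4 = _fixed_draw(
                scenario=4, N_ATL=3_000.0, N_MED=3_000.0, Nb_ATL=3_000.0,
                Nb_MED=3_000.0, t=3_000.0, t1=1_000.0, N_anc=3_000.0,
                mu_msat_locus=np.full(2, 2e-4), mu_msat_mean=2e-4,
            )
            s = simulate_scenario(d4, 8, 8, n_loci=2, seq_len=60, rng=rng)
            he4.append(summary_statistics(s)[2])
        assert kstest(he1, he4).pvalue > 0.01


class TestTimeConversion:
    def test_years_from_generations(self):
        assert generations_to_years(100) == 900.0
        assert generations_to_years(100, generation_time=5) == 500.0
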