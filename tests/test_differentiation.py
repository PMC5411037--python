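"""Differentiation statistics against first-principles oracles."""

import itertools
import math

import numpy as np
import pytest

from bathypop.differentiation import (
    amova,
    fst_weir_cockerham,
    frequency_pca,
    g_test_allelic,
    group_p_distance,
    grouping_search,
    jost_dest,
    jost_dest_from_data,
    mantel_ibd,
    pairwise_matrix,
    phi_st,
    sequence_difference_matrix,
)
from bathypop.io_formats import GenotypeDataset, HaplotypeDataset


def _genotypes(pairs, pops, loci=1):
    pairs = np.asarray(pairs).reshape(len(pairs), loci, 2)
    return GenotypeDataset(
        [f"i{k}" for k in range(len(pairs))], pops, [f"L{l}" for l in range(loci)], pairs
    )


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        ds = _genotypes([[1, 1]] * 8 + [[2, 2]] * 8, ["A"] * 8 + ["B"] * 8)
        assert fst_weir_cockerham(ds)["multilocus"] == pytest.approx(1.0)

    def test_duplicated_population_not_positive(self):
        # the same individuals split into two units: s^2 = 0 exactly
        pairs = [[1, 2], [1, 1], [2, 2], [1, 2]]
        ds = _genotypes(pairs + pairs, ["A"] * 4 + ["B"] * 4)
        assert fst_weir_cockerham(ds)["multilocus"] <= 0.0

    def test_matches_direct_component_sums(self):
        # independent evaluation of a, b, c for a 2-pop, 2-allele case
        pa = [[1, 1], [1, 2], [1, 2], [2, 2], [1, 1]]
        pb = [[2, 2], [1, 2], [2, 2], [2, 2]]
        ds = _genotypes(pa + pb, ["A"] * 5 + ["B"] * 4)
        got = fst_weir_cockerham(ds)["multilocus"]

        r = 2
        ns = np.array([5.0, 4.0])
        nbar = ns.mean()
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        a_sum = bc_sum = 0.0
        for allele in (1, 2):
            arrs = [np.asarray(pa), np.asarray(pb)]
            p_i = np.array([np.mean(x == allele) for x in arrs])
            h_i = np.array([np.mean(np.sum(x == allele, axis=1) == 1) for x in arrs])
            pbar = (ns * p_i).sum() / (r * nbar)
            s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ns * h_i).sum() / (r * nbar)
            a = nbar / nc * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = nbar / (nbar - 1) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            a_sum += a
            bc_sum += a + b + hbar / 2
        assert got == pytest.approx(a_sum / bc_sum, abs=1e-12)

    def test_monomorphic_locus_excluded(self):
        ds = _genotypes(
            [[1, 1, 1, 1], [1, 1, 1, 2], [1, 1, 2, 2], [1, 1, 2, 2]],
            ["A", "A", "B", "B"],
            loci=2,
        )
        res = fst_weir_cockerham(ds)
        assert np.isnan(res["L0"])
        assert np.isfinite(res["multilocus"])


class TestPhiSt:
    def test_fixed_difference_is_one(self):
        hd = HaplotypeDataset.from_strings(
            ["AAAA"] * 5 + ["AAAT"] * 5, localities=["X"] * 5 + ["Y"] * 5
        )
        assert phi_st(hd)[0] == pytest.approx(1.0)

    def test_identical_composition_not_positive(self):
        seqs = ["AAAA", "AAAT", "AATT"]
        hd = HaplotypeDataset.from_strings(
            seqs + seqs, localities=["X"] * 3 + ["Y"] * 3
        )
        assert phi_st(hd)[0] <= 0.0

    def test_single_sequence_unit_rejected(self):
        hd = HaplotypeDataset.from_strings(
            ["AAAA", "AAAT", "AATT"], localities=["X", "X", "Y"]
        )
        with pytest.raises(ValueError, match="Y"):
            phi_st(hd)

    def test_three_unit_case_matches_amova_oracle(self):
        # brute-force two-level AMOVA from explicit sums of squares
        seqs = ["AAAA", "AAAT", "AATT", "TTTT", "TTTA", "AAAA", "ATAT", "ATTT", "AATA"]
        labels = ["X"] * 3 + ["Y"] * 3 + ["Z"] * 3
        hd = HaplotypeDataset.from_strings(seqs, localities=labels)
        got = phi_st(hd)[0]

        def d2(i, j):
            return sum(a != b for a, b in zip(seqs[i], seqs[j]))

        N, P = 9, 3
        ss_total = sum(d2(i, j) for i in range(N) for j in range(N)) / (2 * N)
        ss_within = 0.0
        for g in range(3):
            idx = range(3 * g, 3 * g + 3)
            ss_within += sum(d2(i, j) for i in idx for j in idx) / (2 * 3)
        ms_among = (ss_total - ss_within) / (P - 1)
        ms_within = ss_within / (N - P)
        n_prime = (N - sum(3**2 for _ in range(3)) / N) / (P - 1)
        sigma_a = (ms_among - ms_within) / n_prime
        expected = sigma_a / (sigma_a + ms_within)
        assert got == pytest.approx(expected, abs=1e-12)


class TestJostD:
    def test_disjoint_units_exactly_one(self):
        freqs = np.array([[0.7, 0.3, 0.0, 0.0], [0.0, 0.0, 0.5, 0.5]])
        assert jost_dest(freqs, np.array([40, 40])) == pytest.approx(1.0, abs=1e-12)

    def test_identical_frequencies_near_zero(self):
        freqs = np.array([[0.5, 0.5], [0.5, 0.5]])
        d = jost_dest(freqs, np.array([40, 40]))
        assert d <= 0.0 and d > -0.1  # unbiased estimator noise, not positive

    def test_two_unit_two_allele_hand_evaluation(self):
        n1, n2 = 10.0, 20.0
        p1, p2 = 0.8, 0.3
        freqs = np.array([[p1, 1 - p1], [p2, 1 - p2]])
        ntilde = 2 / (1 / n1 + 1 / n2)
        hs = ntilde / (ntilde - 1) * (
            1 - ((p1**2 + (1 - p1) ** 2) + (p2**2 + (1 - p2) ** 2)) / 2
        )
        pbar = (p1 + p2) / 2
        ht = 1 - (pbar**2 + (1 - pbar) ** 2) + hs / (2 * ntilde)
        expected = 2 * (ht - hs) / (1 - hs)
        assert jost_dest(freqs, np.array([n1, n2])) == pytest.approx(expected, abs=1e-12)

    def test_dataset_haplotype_route(self):
        hd = HaplotypeDataset.from_strings(
            ["AAAA"] * 4 + ["AAAT"] * 4, localities=["X"] * 4 + ["Y"] * 4
        )
        assert jost_dest_from_data(hd) == pytest.approx(1.0)


class TestGTest:
    def test_identical_counts_null(self):
        ds = _genotypes(
            [[1, 2], [1, 1], [1, 2], [1, 1]], ["A", "A", "B", "B"]
        )
        p_locus, p_global = g_test_allelic(ds, ("A", "B"), permutations=200, seed=1)
        assert p_global == pytest.approx(1.0, abs=0.05)

    def test_g_statistic_hand_value(self):
        from bathypop.differentiation import _g_statistic

        # 2x2 table (10,0 / 0,10): G = 2 * 20 * ln(2) = 27.73
        g = _g_statistic(np.array([[10, 0], [0, 10]]))
        assert g == pytest.approx(40 * math.log(2), abs=1e-9)
        assert g == pytest.approx(27.73, abs=0.005)


class TestAmova:
    def test_two_population_fst_equals_phist(self):
        hd = HaplotypeDataset.from_strings(
            ["AAAA", "AAAT", "AATT", "TTAA", "TAAA", "TTTA"],
            localities=["X"] * 3 + ["Y"] * 3,
        )
        assert amova(hd).f_st == pytest.approx(phi_st(hd)[0], abs=1e-12)

    def test_total_variance_is_component_sum(self):
        hd = HaplotypeDataset.from_strings(
            ["AAAA"] * 3 + ["AATT"] * 3 + ["TTAA"] * 3 + ["TTTT"] * 3,
            localities=["P1"] * 3 + ["P2"] * 3 + ["P3"] * 3 + ["P4"] * 3,
        )
        res = amova(hd, {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"})
        assert res.total_variance == pytest.approx(
            res.sigma2_among_groups + res.sigma2_among_pops + res.sigma2_within
        )
        assert res.f_st == pytest.approx(
            (res.sigma2_among_groups + res.sigma2_among_pops) / res.total_variance
        )

    def test_panmictic_pool_indices_near_zero(self, rng):
        seqs = ["AAAA", "AAAT", "AATT", "ATTT"]
        draws = rng.integers(0, 4, size=40)
        hd = HaplotypeDataset.from_strings(
            [seqs[d] for d in draws],
            localities=[f"P{i % 4}" for i in range(40)],
        )
        res = amova(hd, {"P0": "G1", "P1": "G1", "P2": "G2", "P3": "G2"})
        assert abs(res.f_ct) < 0.2
        assert abs(res.f_st) < 0.2

    def test_correct_split_maximizes_fct(self):
        # two internally-identical clusters; enumerate all 2+2 groupings
        hd = HaplotypeDataset.from_strings(
            ["AAAA"] * 3 + ["AAAA"] * 3 + ["TTTT"] * 3 + ["TTTT"] * 3,
            localities=["P1"] * 3 + ["P2"] * 3 + ["P3"] * 3 + ["P4"] * 3,
        )
        candidates = []
        for other in ("P2", "P3", "P4"):
            grouping = {p: ("G1" if p in ("P1", other) else "G2") for p in
                        ("P1", "P2", "P3", "P4")}
            candidates.append(grouping)
        ranked = grouping_search(hd, candidates)
        best = ranked[0].grouping
        assert best["P1"] == best["P2"] and best["P3"] == best["P4"]
        assert best["P1"] != best["P3"]
        assert ranked[0].f_ct == pytest.approx(1.0)

    def test_identical_populations_all_fct_near_zero(self):
        hd = HaplotypeDataset.from_strings(
            ["AAAT", "AATT"] * 6,
            localities=["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4,
        )
        cands = [
            {"P1": "A", "P2": "A", "P3": "B"},
            {"P1": "A", "P2": "B", "P3": "B"},
        ]
        with pytest.warns(UserWarning):
            ranked = grouping_search(hd, cands)
        assert all(abs(r.f_ct) < 0.25 for r in ranked)


class TestMantel:
    def test_exact_linear_relation(self):
        geo = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0))) * 100
        res = mantel_ibd(0.001 * geo, geo, permutations=999, seed=3)
        assert res.slope == pytest.approx(0.001)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.mantel_p <= 0.05

    def test_constant_genetic_matrix(self):
        geo = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        gen = np.full((4, 4), 0.2)
        res = mantel_ibd(gen, geo, permutations=99, seed=1)
        assert res.slope == 0.0 and res.mantel_p == 1.0

    def test_against_exhaustive_enumeration(self, rng):
        # 4x4: exact null distribution over all 24 joint row/col permutations
        def sym(m):
            m = np.triu(m, 1)
            return m + m.T

        gen = sym(rng.random((4, 4)))
        geo = sym(rng.random((4, 4)) + 0.1)
        iu = np.triu_indices(4, 1)
        obs = np.corrcoef(geo[iu], gen[iu])[0, 1]
        hits = 0
        for perm in itertools.permutations(range(4)):
            gp = gen[np.ix_(perm, perm)]
            if np.corrcoef(geo[iu], gp[iu])[0, 1] >= obs - 1e-12:
                hits += 1
        exact = hits / 24
        res = mantel_ibd(gen, geo, permutations=4999, seed=7)
        assert res.mantel_p == pytest.approx(exact, abs=0.05)

    def test_linearized_transform(self):
        geo = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0))) + 1
        np.fill_diagonal(geo, 0)
        gen = np.full((4, 4), 0.5)
        np.fill_diagonal(gen, 0)
        res = mantel_ibd(gen, geo, permutations=99, transform="linearized", seed=1)
        assert res.intercept == pytest.approx(1.0)  # 0.5 / (1 - 0.5)


class TestFrequencyPca:
    def test_variance_fractions_sum_to_one(self, study_mimic):
        gen, mt, _ = study_mimic
        res = frequency_pca(mt)
        assert res.inertia_fractions.sum() == pytest.approx(1.0, abs=1e-6)

    def test_basin_separation_on_first_axis(self, study_mimic):
        gen, mt, _ = study_mimic
        res = frequency_pca(mt, randomizations=99, seed=5)
        med = [i for i, lab in enumerate(res.labels) if lab.startswith("MED")]
        atl = [i for i, lab in enumerate(res.labels) if not lab.startswith("MED")]
        pc1_med = res.coordinates[med, 0]
        pc1_atl = res.coordinates[atl, 0]
        assert max(pc1_med) < min(pc1_atl) or min(pc1_med) > max(pc1_atl)
        assert res.axis_p[0] <= 0.05


class TestGroupPDistance:
    def test_single_difference_fraction(self):
        hd = HaplotypeDataset.from_strings(
            ["A" * 598, "A" * 597 + "G"], localities=["X", "Y"]
        )
        est, _ = group_p_distance(hd, {"X": "a", "Y": "b"}, bootstraps=0)
        assert est * 100 == pytest.approx(0.167, abs=5e-4)

    def test_zero_se_for_fixed_monomorphic_groups(self):
        hd = HaplotypeDataset.from_strings(
            ["AAAA"] * 3 + ["AAAT"] * 3, localities=["X"] * 3 + ["Y"] * 3
        )
        est, se = group_p_distance(hd, {"X": "a", "Y": "b"}, bootstraps=50, seed=2)
        assert est == pytest.approx(0.25)
        assert se == pytest.approx(0.0, abs=1e-12) or se >= 0  # site bootstrap SE
        # haplotype weighting agrees when groups are monomorphic
        est_h, _ = group_p_distance(
            hd, {"X": "a", "Y": "b"}, bootstraps=0, weighting="haplotypes"
        )
        assert est_h == pytest.approx(est)


class TestPairwiseMatrix:
    def test_fdr_decisions_monotone_in_alpha(self, study_mimic):
        _, mt, _ = study_mimic
        mat = pairwise_matrix(
            mt, "phist", permutations=199, alpha_levels=(0.05, 0.01, 0.001), seed=9
        )
        sig05 = mat.p_fdr_significant[0.05]
        sig01 = mat.p_fdr_significant[0.01]
        sig001 = mat.p_fdr_significant[0.001]
        assert (sig01 <= sig05).all() and (sig001 <= sig01).all()

    def test_cross_basin_pairs_significant_within_not(self, study_mimic):
        _, mt, _ = study_mimic
        mat = pairwise_matrix(mt, "phist", permutations=199, seed=9)
        atl = [p for p in mat.labels if not p.startswith("MED")]
        med = [p for p in mat.labels if p.startswith("MED")]
        for a in atl:
            for m in med:
                assert mat.significant(a, m, 0.05), (a, m)
        assert not mat.significant("MED1", "MED2", 0.05)
        assert not mat.significant("MAR1", "ROC", 0.05)
        assert not mat.significant("MAR2", "MAR3", 0.05)
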