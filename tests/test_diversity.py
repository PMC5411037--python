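"""Diversity statistics against hand computations and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bathypop.diversity import (
    allelic_richness,
    fis,
    haplotype_diversity,
    heterozygosity,
    hwe_exact_test,
    nucleotide_diversity,
    segregating_sites,
    total_gene_diversity,
)
from bathypop.io_formats import GenotypeDataset, HaplotypeDataset


def _genotypes(pairs, pops=None, loci=1):
    pairs = np.asarray(pairs).reshape(len(pairs), loci, 2)
    pops = pops or ["P"] * len(pairs)
    return GenotypeDataset(
        [f"i{k}" for k in range(len(pairs))], pops, [f"L{l}" for l in range(loci)], pairs
    )


class TestHeterozygosity:
    def test_monomorphic_zero(self):
        ds = _genotypes([[1, 1], [1, 1]])
        row = heterozygosity(ds, "P").iloc[0]
        assert row["HO"] == 0.0 and row["HE"] == 0.0

    def test_two_heterozygotes_unbiased(self):
        # n=2 diploids, both A/B: HE = (4/3)(1 - 0.5) = 0.6667
        ds = _genotypes([[1, 2], [1, 2]])
        row = heterozygosity(ds, "P").iloc[0]
        assert row["HO"] == 1.0
        assert row["HE"] == pytest.approx(2 / 3, abs=1e-12)

    def test_he_converges_to_expected(self, rng):
        # large sample at known frequencies: HE -> 1 - sum p^2
        p = np.array([0.5, 0.3, 0.2])
        genes = rng.choice(3, size=(3000, 2), p=p) + 1
        ds = _genotypes(genes)
        he = heterozygosity(ds, "P")["HE"].iloc[0]
        assert he == pytest.approx(1 - np.sum(p**2), abs=0.01)

    def test_unscored_cell_is_nan_not_zero(self):
        ds = _genotypes([[0, 0], [0, 0]])
        assert np.isnan(heterozygosity(ds, "P")["HE"].iloc[0])

    def test_ht_uses_pooled_frequencies(self):
        ds = _genotypes([[1, 1], [2, 2]], pops=["A", "B"])
        # pooled: p = q = 0.5 over 4 genes -> HT = (4/3)(1-0.5)
        assert total_gene_diversity(ds).iloc[0] == pytest.approx(2 / 3)


class TestAllelicRichness:
    def test_g_equals_n_gives_allele_count(self):
        ds = _genotypes([[1, 2], [3, 3], [1, 1]])
        assert allelic_richness(ds, 6, "P").iloc[0] == pytest.approx(3.0)

    def test_counts_9_1_at_g2(self):
        # Rs = 1 + (1 - C(9,2)/C(10,2)) = 1 + (1 - 36/45) = 1.2
        pairs = [[1, 1]] * 4 + [[1, 2]]
        ds = _genotypes(pairs)
        assert allelic_richness(ds, 2, "P").iloc[0] == pytest.approx(1.2)

    def test_monomorphic_is_one(self):
        ds = _genotypes([[1, 1]] * 5)
        for g in (2, 5, 10):
            assert allelic_richness(ds, g, "P").iloc[0] == pytest.approx(1.0)

    def test_monotone_in_g_and_bounded_at_two(self, rng):
        genes = rng.integers(1, 5, size=(20, 2))
        ds = _genotypes(genes)
        values = [allelic_richness(ds, g, "P").iloc[0] for g in range(2, 41)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert 1.0 <= values[0] <= 2.0

    def test_g_too_large_names_cell(self):
        ds = _genotypes([[1, 2]])
        with pytest.raises(ValueError, match="L0"):
            allelic_richness(ds, 3, "P")


class TestFis:
    def test_hardy_weinberg_proportions_near_zero(self):
        # exact HW counts for p = q = 0.5, n = 500
        pairs = [[1, 1]] * 125 + [[1, 2]] * 250 + [[2, 2]] * 125
        ds = _genotypes(pairs)
        assert abs(fis(ds, "P")["multilocus"]) < 0.02

    def test_all_homozygous_is_one(self):
        ds = _genotypes([[1, 1], [2, 2]] * 5)
        assert fis(ds, "P")["multilocus"] == pytest.approx(1.0)

    def test_matches_direct_variance_component_sums(self):
        # independent evaluation of the within-population b and c sums
        pairs = [[1, 1], [1, 2], [2, 2], [1, 2], [1, 1], [1, 2], [2, 2], [1, 1]]
        ds = _genotypes(pairs)
        got = fis(ds, "P").iloc[0]
        n = len(pairs)
        arr = np.asarray(pairs)
        bc = c = 0.0
        for allele in (1, 2):
            p = np.mean(arr == allele)
            h = np.mean(np.sum(arr == allele, axis=1) == 1)
            b_a = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            bc += b_a + h / 2
            c += h / 2
        assert got == pytest.approx(1 - c / bc, abs=1e-12)

    def test_monomorphic_unit_flagged(self):
        ds = _genotypes([[1, 1]] * 4)
        assert np.isnan(fis(ds, "P")["multilocus"])


def _levene_prob(hom1, het, hom2):
    """Independent Levene probability for a biallelic genotype table."""
    n = hom1 + het + hom2
    n1 = 2 * hom1 + het
    n2 = 2 * hom2 + het
    return (
        math.factorial(n)
        * math.factorial(n1)
        * math.factorial(n2)
        * 2**het
        / (
            math.factorial(2 * n)
            * math.factorial(hom1)
            * math.factorial(het)
            * math.factorial(hom2)
        )
    )


class TestHweExact:
    def test_monomorphic_p_one(self):
        ds = _genotypes([[1, 1]] * 5)
        assert hwe_exact_test(ds, "P", 0) == 1.0

    @pytest.mark.parametrize("het_obs", [1, 3, 5])
    def test_biallelic_matches_enumeration_oracle(self, het_obs):
        # n=5, allele counts (5,5): heterozygote count can be 1, 3 or 5
        hom1 = (5 - het_obs) // 2
        pairs = [[1, 1]] * hom1 + [[1, 2]] * het_obs + [[2, 2]] * hom1
        ds = _genotypes(pairs)
        probs = {h: _levene_prob((5 - h) // 2, h, (5 - h) // 2) for h in (1, 3, 5)}
        expected = sum(p for p in probs.values() if p <= probs[het_obs] + 1e-12)
        assert hwe_exact_test(ds, "P", 0) == pytest.approx(expected, abs=1e-9)

    def test_monte_carlo_close_to_enumeration(self):
        # 3-allele toy: exact p by enumerating all genotype tables
        pairs = [[1, 1], [1, 2], [2, 3], [3, 3], [1, 3], [2, 2]]
        ds = _genotypes(pairs)
        arr = np.asarray(pairs)
        genes = arr.ravel()
        counts = {a: int(np.sum(genes == a)) for a in (1, 2, 3)}
        n = len(pairs)

        def table_prob(tab):
            het = tab[(0, 0, 1)] + tab[(0, 2, 1)] + tab[(1, 2, 1)]
            denom = 1.0
            for v in tab.values():
                denom *= math.factorial(v)
            return (
                math.factorial(n)
                * math.prod(math.factorial(c) for c in counts.values())
                * 2**het
                / (math.factorial(2 * n) * denom)
            )

        # enumerate genotype tables (n11, n12, n13, n22, n23, n33)
        probs = []
        obs_prob = None
        for n12 in range(min(counts[1], counts[2]) + 1):
            for n13 in range(min(counts[1] - n12, counts[3]) + 1):
                if (counts[1] - n12 - n13) % 2:
                    continue
                for n23 in range(min(counts[2] - n12, counts[3] - n13) + 1):
                    if (counts[2] - n12 - n23) % 2 or (counts[3] - n13 - n23) % 2:
                        continue
                    tab = {
                        (0, 0, 0): (counts[1] - n12 - n13) // 2,
                        (0, 0, 1): n12,
                        (0, 2, 1): n13,
                        (1, 1, 0): (counts[2] - n12 - n23) // 2,
                        (1, 2, 1): n23,
                        (2, 2, 0): (counts[3] - n13 - n23) // 2,
                    }
                    probs.append(table_prob(tab))
        # observed table: hets n12=1 (1,2), n13=1 (1,3), n23=1 (2,3)
        obs_prob = table_prob(
            {(0, 0, 0): 1, (0, 0, 1): 1, (0, 2, 1): 1, (1, 1, 0): 1, (1, 2, 1): 1, (2, 2, 0): 1}
        )
        exact = sum(p for p in probs if p <= obs_prob + 1e-12)
        assert abs(sum(probs) - 1.0) < 1e-9  # enumeration is complete
        mc = hwe_exact_test(ds, "P", 0, n_mc=20_000, seed=11)
        se = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(mc - exact) < 3 * se + 1e-3


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts, expected",
        [((6, 3, 1), 0.600), ((46, 2, 1), 0.119), ((15, 2, 1), 0.307), ((30,), 0.000)],
    )
    def test_reported_three_decimal_values(self, counts, expected):
        assert round(haplotype_diversity(counts), 3) == pytest.approx(expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 40), min_size=2, max_size=8))
    def test_permutation_invariant(self, counts):
        a = haplotype_diversity(counts)
        b = haplotype_diversity(sorted(counts, reverse=True))
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 1.0

    def test_singleton_increases_monomorphic_diversity(self):
        assert haplotype_diversity([10, 1]) > haplotype_diversity([11])


class TestNucleotideDiversity:
    def test_identical_sequences_zero(self):
        ds = HaplotypeDataset.from_strings(["ACGT"] * 4)
        assert nucleotide_diversity(ds) == 0.0

    def test_single_difference(self):
        ds = HaplotypeDataset.from_strings(["A" * 613, "A" * 612 + "G"])
        assert nucleotide_diversity(ds) == pytest.approx(1 / 613)

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(50):
            n, L = rng.integers(3, 10), rng.integers(5, 30)
            seqs = ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)]
            ds = HaplotypeDataset.from_strings(seqs)
            acc = [
                sum(a != b for a, b in zip(seqs[i], seqs[j])) / L
                for i, j in itertools.combinations(range(n), 2)
            ]
            assert nucleotide_diversity(ds) == pytest.approx(np.mean(acc))

    def test_pairwise_deletion_of_ambiguous_sites(self):
        ds = HaplotypeDataset.from_strings(["ANGT", "ACGA", "ACGT"])
        # pair (0,1): 3 comparable sites, 1 diff; (0,2): 3, 0; (1,2): 4, 1
        expected = np.mean([1 / 3, 0 / 3, 1 / 4])
        assert nucleotide_diversity(ds) == pytest.approx(expected)


class TestSegregatingSites:
    def test_identical_no_sites(self):
        ds = HaplotypeDataset.from_strings(["ACGT", "ACGT"])
        assert segregating_sites(ds).S == 0

    def test_single_transition(self):
        ds = HaplotypeDataset.from_strings(["ACGT", "ACAT"])
        res = segregating_sites(ds)
        assert (res.S, res.transitions, res.transversions) == (1, 1, 0)

    def test_triallelic_counted_but_unclassified(self):
        ds = HaplotypeDataset.from_strings(["AAAA", "AAAC", "AAAG"])
        with pytest.warns(UserWarning, match="excluded"):
            res = segregating_sites(ds)
        assert res.S == 1
        assert res.transitions == 0 and res.transversions == 0
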