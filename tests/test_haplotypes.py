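"""Haplotype collapsing, diversity statistics and the connection limit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylodeme.haplotypes import (collapse_haplotypes, haplotype_diversity,
                                  nucleotide_diversity, classify_segregating_sites,
                                  connection_limit, parsimony_probability)


class TestCollapse:
    def test_direct_identity(self):
        aln = {"s1": "ACGT", "s2": "ACGT", "s3": "ACGA"}
        dm = {k: "D" for k in aln}
        t = collapse_haplotypes(aln, dm)
        assert sorted(t.total_counts()) == [1, 2]

    def test_all_identical(self):
        aln = {f"s{i}": "ACGT" for i in range(10)}
        t = collapse_haplotypes(aln, {k: "D" for k in aln})
        assert list(t.total_counts()) == [10]

    def test_two_deme_count_matrix_matches_hand_enumeration(self, toy_alignment):
        aln, dm = toy_alignment
        t = collapse_haplotypes(aln, dm)
        # hand enumeration: ACGTACGT x{a1,a2} y{b1}; ACGAACGT x{a3} y{b2}; TCGAACGT y{b3}
        got = {t.sequences[h]: tuple(t.counts.loc[h, ["X", "Y"]]) for h in t.haplotype_ids}
        assert got == {"ACGTACGT": (2, 1), "ACGAACGT": (1, 1), "TCGAACGT": (0, 1)}
        assert (t.counts.sum(axis=0) == [3, 3]).all()

    def test_case_insensitive(self):
        t = collapse_haplotypes({"a": "acgt", "b": "ACGT"}, {"a": "D", "b": "D"})
        assert len(t.haplotype_ids) == 1

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            collapse_haplotypes({"a": "ACG", "b": "ACGT"}, {"a": "D", "b": "D"})

    def test_missing_deme_rejected(self):
        with pytest.raises(ValueError, match="deme map"):
            collapse_haplotypes({"a": "ACGT", "b": "ACGT"}, {"a": "D"})

    def test_ambiguity_codes_demand_phased_input(self):
        with pytest.raises(ValueError, match="phased"):
            collapse_haplotypes({"a": "ACRT"}, {"a": "D"})

    def test_gap_columns_excluded_from_statistics(self):
        aln = {"a": "A-GT", "b": "ACGT"}
        t = collapse_haplotypes(aln, {"a": "D", "b": "D"})
        assert list(t.included_columns) == [0, 2, 3]
        assert len(t.haplotype_ids) == 2          # identity on the full string
        assert t.distance_matrix().iloc[0, 1] == 0  # but distance on clean columns


class TestDiversity:
    def test_monomorphic_h_zero(self):
        assert haplotype_diversity([5]) == 0.0

    def test_two_singletons_h_one(self):
        assert haplotype_diversity([1, 1]) == pytest.approx(1.0)

    def test_three_one_split(self):
        # (4/3) * (1 - 0.5625 - 0.0625) by hand
        assert haplotype_diversity([3, 1]) == pytest.approx(0.5)

    def test_h_requires_two_sequences(self):
        with pytest.raises(ValueError):
            haplotype_diversity([1])

    def test_pi_monomorphic(self):
        aln = {f"s{i}": "AAAA" for i in range(4)}
        t = collapse_haplotypes(aln, {k: "D" for k in aln})
        assert nucleotide_diversity(t) == 0.0

    def test_pi_single_pair(self):
        seq = "A" * 99
        t = collapse_haplotypes({"a": seq + "C", "b": seq + "G"}, {"a": "D", "b": "D"})
        assert nucleotide_diversity(t) == pytest.approx(0.01)

    def test_pi_matches_brute_force_pair_enumeration(self):
        L = 219
        s1 = "A" * L
        s2 = "C" * 3 + "A" * (L - 3)
        aln = {"a": s1, "b": s1, "c": s2, "d": s2}
        t = collapse_haplotypes(aln, {k: "D" for k in aln})
        seqs = list(aln.values())
        diffs = [sum(x != y for x, y in zip(seqs[i], seqs[j]))
                 for i in range(4) for j in range(i + 1, 4)]
        assert nucleotide_diversity(t) == pytest.approx(np.mean(diffs) / L)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(perm=st.permutations(list(range(6))))
    def test_h_and_pi_invariant_under_relabeling(self, perm, toy_alignment):
        aln, dm = toy_alignment
        ids = list(aln)
        renamed = {f"r{i}": aln[ids[p]] for i, p in enumerate(perm)}
        dm2 = {f"r{i}": dm[ids[p]] for i, p in enumerate(perm)}
        t1 = collapse_haplotypes(aln, dm)
        t2 = collapse_haplotypes(renamed, dm2)
        assert haplotype_diversity(t1.total_counts()) == pytest.approx(
            haplotype_diversity(t2.total_counts()))
        assert nucleotide_diversity(t1) == pytest.approx(nucleotide_diversity(t2))

    def test_pi_invariant_under_column_permutation(self, toy_alignment):
        aln, dm = toy_alignment
        rng = np.random.default_rng(0)
        perm = rng.permutation(8)
        shuffled = {k: "".join(v[i] for i in perm) for k, v in aln.items()}
        assert nucleotide_diversity(collapse_haplotypes(shuffled, dm)) == pytest.approx(
            nucleotide_diversity(collapse_haplotypes(aln, dm)))


class TestSegregatingSites:
    def test_monomorphic(self):
        aln = {f"s{i}": "AAAA" for i in range(5)}
        assert classify_segregating_sites(aln) == (0, 0)

    def test_hand_classified_toy(self):
        aln = {"1": "AAT", "2": "AAT", "3": "AAC", "4": "GAC"}
        # site 1: one G (singleton); site 3: T/T vs C/C (parsimony informative)
        assert classify_segregating_sites(aln) == (1, 1)

    def test_biallelic_sites_partition_into_classes(self, coi_like_dataset):
        aln, dm, _ = coi_like_dataset
        mat = np.vstack([np.frombuffer(s.encode(), np.uint8) for s in aln.values()])
        biallelic = variable = 0
        for j in range(mat.shape[1]):
            u = np.unique(mat[:, j])
            if len(u) > 1:
                variable += 1
            if len(u) == 2:
                biallelic += 1
        singles, pis = classify_segregating_sites(aln)
        if biallelic == variable:
            assert singles + pis == variable

    def test_triallelic_site_counts_each_unique_variant(self):
        aln = {"1": "A", "2": "A", "3": "C", "4": "G"}
        assert classify_segregating_sites(aln) == (2, 0)


class TestConnectionLimit:
    def test_limit_capped_at_locus_length_for_tiny_confidence(self):
        assert connection_limit(10, 1e-12) == 10

    def test_monotone_in_length(self):
        limits = [connection_limit(L, 0.95) for L in (100, 300, 604)]
        assert limits == sorted(limits)

    def test_matches_monte_carlo_parsimony_oracle_at_604(self):
        """Oracle: place j mutations uniformly on 604 sites with random new
        bases; the connection is parsimonious iff the observed distance
        equals j (any repeated hit shortens the path)."""
        rng = np.random.default_rng(2024)
        L, reps = 604, 100_000
        def mc_prob(j):
            sites = np.sort(rng.integers(0, L, size=(reps, j)), axis=1)
            # distance shrinks iff any site hit twice
            hit_twice = (np.diff(sites, axis=1) == 0).any(axis=1)
            return 1.0 - hit_twice.mean()
        j = 1
        while mc_prob(j + 1) >= 0.95:
            j += 1
        assert connection_limit(604, 0.95) == j

    def test_parsimony_probability_decreasing_in_steps(self):
        probs = [parsimony_probability(j, 604) for j in range(1, 20)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            connection_limit(0, 0.95)
        with pytest.raises(ValueError):
            connection_limit(100, 1.0)
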