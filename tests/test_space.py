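"""Genotype-space primitives: neighbourhoods, shells, tabulation, IO."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcorr.io import MalformedTableError, read_gpmap, write_gpmap
from gpcorr.space import (
    GenotypeSpace,
    GPMap,
    InvalidGenotypeError,
    UnsupportedModeError,
    estimate_frequencies,
    mutant_shell,
    neighbours,
    shell_size,
    tabulate,
)


class TestNeighbours:
    @pytest.mark.parametrize(
        "g, alphabet, expected_n",
        [
            ("00", "01", 2),
            ("AAAA", "ABCDEFGHIJKLMNOPQRSTUVWXYZ", 100),  # word game: 100 per word
            ("AUGC", "AUGC", 12),
        ],
    )
    def test_count_and_distance(self, g, alphabet, expected_n):
        sp = GenotypeSpace(alphabet, len(g))
        nb = neighbours(g, sp)
        assert len(nb) == expected_n == sp.n_neighbours
        assert len(set(nb)) == expected_n
        assert all(sum(a != b for a, b in zip(g, h)) == 1 for h in nb)
        assert g not in nb

    def test_binary_pair(self):
        sp = GenotypeSpace("01", 2)
        assert set(neighbours("00", sp)) == {"10", "01"}

    def test_invalid_character_rejected(self):
        sp = GenotypeSpace("01", 2)
        with pytest.raises(InvalidGenotypeError):
            neighbours("0X", sp)
        with pytest.raises(InvalidGenotypeError):
            neighbours("000", sp)

    @pytest.mark.parametrize("K, L", [(2, 3), (2, 4), (3, 3), (3, 4)])
    def test_symmetry_exhaustive(self, K, L):
        """h in N(g) iff g in N(h), over the whole space."""
        sp = GenotypeSpace("012"[:K], L)
        for r in range(sp.n_genotypes):
            g = sp.genotype(r)
            for h in neighbours(g, sp):
                assert g in neighbours(h, sp)

    def test_rank_array_matches_string_route(self):
        sp = GenotypeSpace("AUGC", 5)
        ranks = np.array([0, 17, 1023, sp.n_genotypes - 1])
        arr = sp.neighbour_ranks(ranks)
        for i, r in enumerate(ranks):
            expected = [sp.rank(h) for h in neighbours(sp.genotype(int(r)), sp)]
            assert arr[i].tolist() == expected


class TestMutantShell:
    def test_full_shell_is_unique_and_exact_distance(self):
        sp = GenotypeSpace("01", 2)
        assert mutant_shell("00", 2, sp) == ["11"]

    def test_radius_one_equals_neighbours(self):
        sp = GenotypeSpace("AUGC", 4)
        assert mutant_shell("AUGC", 1, sp) == neighbours("AUGC", sp)

    @pytest.mark.parametrize("K, L", [(2, 4), (3, 4), (4, 4)])
    def test_shell_size_closed_form_vs_enumeration(self, K, L):
        sp = GenotypeSpace("0123"[:K], L)
        g = sp.genotype(0)
        for n in range(1, L + 1):
            shell = mutant_shell(g, n, sp)
            assert len(shell) == shell_size(sp, n) == math.comb(L, n) * (K - 1) ** n
            assert len(set(shell)) == len(shell)
            assert all(sum(a != b for a, b in zip(g, h)) == n for h in shell)

    def test_shell_sizes_partition_the_space(self):
        # sum over n of C(L,n)(K-1)^n = K^L
        for K in (2, 3, 4):
            for L in (1, 3, 6):
                sp = GenotypeSpace("0123"[:K], L)
                assert sum(shell_size(sp, n) for n in range(L + 1)) == sp.n_genotypes

    def test_sampling_is_reproducible_and_on_shell(self):
        sp = GenotypeSpace("AUGC", 12)
        a = mutant_shell("AUGCAUGCAUGC", 3, sp, sample_size=50, seed=7)
        b = mutant_shell("AUGCAUGCAUGC", 3, sp, sample_size=50, seed=7)
        assert a == b
        assert all(sum(x != y for x, y in zip("AUGCAUGCAUGC", h)) == 3 for h in a)
        assert shell_size(sp, 3) == 5940

    def test_radius_out_of_range(self):
        sp = GenotypeSpace("01", 4)
        with pytest.raises(ValueError):
            mutant_shell("0000", 5, sp)


class TestTabulate:
    def test_two_genotype_map(self):
        sp = GenotypeSpace("01", 1)
        m = GPMap.from_assignment(sp, {"0": "A", "1": "B"})
        t = tabulate(m)
        assert t.count("A") == t.count("B") == 1
        assert t.frequency("A") == 0.5

    def test_single_phenotype_normalisation(self):
        sp = GenotypeSpace("01", 5)
        m = GPMap(sp, codes=np.zeros(32, dtype=np.int32), labels=["only"])
        t = tabulate(m)
        assert t.n_phenotypes == 1 and t.frequency("only") == 1.0

    def test_frequencies_sum_to_one(self, random_map_k4):
        t = tabulate(random_map_k4)
        assert abs(t.frequencies.sum() - 1.0) <= 1e-12
        assert int(t.counts.sum()) == random_map_k4.space.n_genotypes

    def test_permutation_invariance(self, small_random_map):
        """Relabelling genotypes leaves the redundancy multiset unchanged."""
        m = small_random_map
        rng = np.random.default_rng(1)
        perm = rng.permutation(m.space.n_genotypes)
        m2 = GPMap(m.space, codes=m.codes[perm], labels=m.labels)
        assert sorted(tabulate(m).counts) == sorted(tabulate(m2).counts)

    def test_sampled_mode_refused(self):
        sp = GenotypeSpace("01", 3)
        m = GPMap.from_oracle(sp, lambda g: "x")
        with pytest.raises(UnsupportedModeError):
            tabulate(m)


class TestEstimateFrequencies:
    def test_constant_map_estimates_one(self):
        sp = GenotypeSpace("01", 4)
        m = GPMap.from_oracle(sp, lambda g: "x")
        t = estimate_frequencies(m, 100, seed=0)
        assert t.frequency("x") == 1.0

    def test_uniform_two_phenotype_within_3se(self):
        sp = GenotypeSpace("01", 10)
        m = GPMap.from_oracle(sp, lambda g: "even" if g.count("1") % 2 == 0 else "odd")
        t = estimate_frequencies(m, 10_000, seed=3)
        f = t.frequency("even")
        se = math.sqrt(0.5 * 0.5 / 10_000)
        assert abs(f - 0.5) <= 3 * se

    def test_converges_to_tabulate(self, small_random_map):
        exact = tabulate(small_random_map)
        est = estimate_frequencies(small_random_map, 20_000, seed=5)
        for p, f in zip(exact.labels, exact.frequencies):
            se = math.sqrt(f * (1 - f) / 20_000)
            assert abs(est.frequency(p) - f) <= 4 * se + 1e-9


class TestRankCodec:
    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=4**6 - 1))
    def test_rank_roundtrip(self, r):
        sp = GenotypeSpace("AUGC", 6)
        assert sp.rank(sp.genotype(r)) == r


class TestMapIO:
    def test_roundtrip(self, tmp_path, small_random_map):
        path = tmp_path / "map.tsv"
        write_gpmap(small_random_map, path)
        back = read_gpmap(path, alphabet="01")
        assert back.space.L == small_random_map.space.L
        assert [
            back.phenotype(back.space.genotype(r)) for r in range(back.space.n_genotypes)
        ] == [
            small_random_map.phenotype(small_random_map.space.genotype(r))
            for r in range(small_random_map.space.n_genotypes)
        ]

    def test_gzip_roundtrip(self, tmp_path, small_random_map):
        path = tmp_path / "map.tsv.gz"
        write_gpmap(small_random_map, path)
        back = read_gpmap(path)
        assert tabulate(back).n_phenotypes == tabulate(small_random_map).n_phenotypes

    def test_partial_table_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("genotype\tphenotype\n00\tA\n01\tB\n")
        with pytest.raises(MalformedTableError):
            read_gpmap(path)  # 2 rows over alphabet {0,1}, L=2: needs 4

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("geno\tpheno\n0\tA\n1\tB\n")
        with pytest.raises(MalformedTableError):
            read_gpmap(path)
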