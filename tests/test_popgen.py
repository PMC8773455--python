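"""Diversity statistics and p-distance matrices vs brute-force oracles."""

import logging
from itertools import combinations

import numpy as np
import pytest

from conftest import make_matrix, random_matrix
from mtlineage.coords import HVS1
from mtlineage.popgen import (
    build_aligned_matrix,
    build_distance_matrix,
    haplotype_diversity,
    mean_p_distance,
    nucleotide_diversity,
    segregating_sites,
    usable_columns,
)
from mtlineage.variants import HaplotypeProfile, parse_variant

# ---------------------------------------------------------------------------
# independent oracles


def oracle_usable(rows):
    L = len(rows[0])
    return [
        j for j in range(L)
        if all(r[j] not in "-N" for r in rows)
    ]


def oracle_S(rows, cols):
    return sum(len({r[j] for r in rows}) > 1 for j in cols)


def oracle_hd(rows, cols):
    n = len(rows)
    keys = ["".join(r[j] for j in cols) for r in rows]
    counts = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    return n * (1 - sum((c / n) ** 2 for c in counts.values())) / (n - 1)


def oracle_pi(rows, cols):
    n = len(rows)
    total = sum(
        sum(rows[i][j] != rows[k][j] for j in cols)
        for i, k in combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2 * len(cols))


def oracle_p_distance(rows_a, rows_b, same_group):
    pairs = (
        list(combinations(range(len(rows_a)), 2))
        if same_group
        else [(i, j) for i in range(len(rows_a)) for j in range(len(rows_b))]
    )
    vals = []
    for i, j in pairs:
        a, b = rows_a[i], (rows_a if same_group else rows_b)[j]
        comp = [(x, y) for x, y in zip(a, b) if x not in "-N" and y not in "-N"]
        vals.append(sum(x != y for x, y in comp) / len(comp))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------


class TestUsableColumns:
    def test_single_n_excludes_only_that_column(self):
        m = make_matrix(["ACGT", "ANGT"])
        assert list(usable_columns(m)) == [0, 2, 3]

    def test_clean_matrix_keeps_all(self):
        m = make_matrix(["ACGT", "TGCA"])
        assert list(usable_columns(m)) == [0, 1, 2, 3]

    def test_matches_column_scan_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            m = random_matrix(rng, 6, 30, n_frac=0.05)
            rows = ["".join(r) for r in m.data]
            assert list(usable_columns(m)) == oracle_usable(rows)


class TestSegregatingSites:
    def test_identical_rows_zero(self):
        assert segregating_sites(make_matrix(["ACGT"] * 4)) == 0

    def test_two_rows_three_diffs(self):
        assert segregating_sites(make_matrix(["AAAAA", "TTTAA"])) == 3

    def test_matches_scan_oracle(self):
        rng = np.random.default_rng(22)
        m = random_matrix(rng, 8, 30, alphabet="AC")
        rows = ["".join(r) for r in m.data]
        cols = oracle_usable(rows)
        assert segregating_sites(m) == oracle_S(rows, cols)


class TestHaplotypeDiversity:
    def test_identical_rows_zero(self):
        assert haplotype_diversity(make_matrix(["ACGT"] * 5)) == 0.0

    def test_all_distinct_is_one(self):
        m = make_matrix(["AAAA", "AAAT", "AATT", "ATTT", "TTTT", "TTTA", "TTAA"])
        assert haplotype_diversity(m) == pytest.approx(1.0, abs=1e-12)

    def test_counts_2_1_1(self):
        m = make_matrix(["AAAA", "AAAA", "AAAT", "TTTT"])
        assert haplotype_diversity(m) == pytest.approx((4 / 3) * (1 - 6 / 16), abs=1e-12)

    def test_n_below_two_errors(self):
        with pytest.raises(ValueError):
            haplotype_diversity(make_matrix(["ACGT"]))


class TestNucleotideDiversity:
    def test_identical_rows_zero(self):
        assert nucleotide_diversity(make_matrix(["ACGT"] * 3)) == 0.0

    def test_two_rows_closed_form(self):
        a = "A" * 100
        b = "T" * 2 + "A" * 98
        assert nucleotide_diversity(make_matrix([a, b])) == pytest.approx(0.02, abs=1e-15)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            m = random_matrix(rng, 6, 50)
            rows = ["".join(r) for r in m.data]
            cols = oracle_usable(rows)
            assert nucleotide_diversity(m) == pytest.approx(
                oracle_pi(rows, cols), abs=1e-12
            )

    def test_zero_usable_columns_errors(self):
        with pytest.raises(ValueError, match="usable"):
            nucleotide_diversity(make_matrix(["N", "A"]))


class TestPermutationInvariance:
    def test_hd_pi_invariant_under_row_and_column_shuffles(self):
        rng = np.random.default_rng(24)
        m = random_matrix(rng, 8, 20)
        hd, pi = haplotype_diversity(m), nucleotide_diversity(m)
        perm_rows = rng.permutation(m.n)
        perm_cols = rng.permutation(m.data.shape[1])
        shuffled = make_matrix(
            ["".join(r) for r in m.data[perm_rows][:, perm_cols]]
        )
        assert haplotype_diversity(shuffled) == pytest.approx(hd, abs=1e-12)
        assert nucleotide_diversity(shuffled) == pytest.approx(pi, abs=1e-12)

    def test_pi_bounded_by_s_over_l(self):
        rng = np.random.default_rng(25)
        for _ in range(10):
            m = random_matrix(rng, 6, 30, alphabet="AG")
            cols = usable_columns(m)
            assert nucleotide_diversity(m) <= oracle_S(
                ["".join(r) for r in m.data], range(m.data.shape[1])
            ) / len(cols) + 1e-12


class TestPDistance:
    def test_identical_singletons_zero(self):
        m = make_matrix(["ACGT", "ACGT"], ["a", "b"])
        assert mean_p_distance(m, "a", "b") == 0.0

    def test_hand_computed_toy(self):
        m = make_matrix(["AAAA", "AAAT", "TTTT"], ["a", "b", "b"])
        # pairs a-b: d=1/4; a-b2: d=4/4 -> mean 0.625
        assert mean_p_distance(m, "a", "b") == pytest.approx(0.625, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(26)
        m = random_matrix(rng, 8, 20, populations=["a"] * 4 + ["b"] * 4)
        assert mean_p_distance(m, "a", "b") == mean_p_distance(m, "b", "a")

    def test_pairwise_deletion_oracle(self):
        rng = np.random.default_rng(27)
        m = random_matrix(
            rng, 8, 25, n_frac=0.08, populations=["a"] * 3 + ["b"] * 5
        )
        rows = ["".join(r) for r in m.data]
        assert mean_p_distance(m, "a", "b") == pytest.approx(
            oracle_p_distance(rows[:3], rows[3:], False), abs=1e-12
        )
        assert mean_p_distance(m, "b", "b") == pytest.approx(
            oracle_p_distance(rows[3:], None, True), abs=1e-12
        )

    def test_no_comparable_sites_errors(self):
        m = make_matrix(["AN", "NA"], ["a", "b"])
        with pytest.raises(ValueError, match="no comparable"):
            mean_p_distance(m, "a", "b")


class TestDistanceMatrix:
    def test_three_populations(self):
        rng = np.random.default_rng(28)
        m = random_matrix(rng, 9, 30, populations=["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        dm = build_distance_matrix(m, min_n=1)
        assert dm.labels == ["a", "b", "c"]
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)
        # elementwise oracle
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert dm.values[i, j] == pytest.approx(
                        mean_p_distance(m, a, b), abs=1e-15
                    )

    def test_small_population_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(29)
        m = random_matrix(
            rng, 70, 20, populations=["big1"] * 30 + ["big2"] * 30 + ["tiny"] * 10
        )
        with caplog.at_level(logging.WARNING):
            dm = build_distance_matrix(m, min_n=30)
        assert dm.labels == ["big1", "big2"]
        assert any("tiny" in r.message for r in caplog.records)

    def test_fewer_than_two_survivors_errors(self):
        m = make_matrix(["ACGT", "ACGA"], ["a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            build_distance_matrix(m, min_n=2)


class TestBuildAlignedMatrix:
    def test_substitution_deletion_insertion_materialisation(self, reference):
        profiles = [
            HaplotypeProfile("s1", "p", HVS1, [parse_variant("16189C")]),
            HaplotypeProfile(
                "s2", "p", HVS1,
                [parse_variant("16051del"), parse_variant("16193.1C")],
            ),
        ]
        m = build_aligned_matrix(profiles, reference, HVS1)
        cols = dict(zip(m.columns, range(len(m.columns))))
        assert m.data[0, cols[(16189, 0)]] == "C"
        assert m.data[1, cols[(16051, 0)]] == "-"
        # insertion column exists right after its anchor, gap for s1
        j = cols[(16193, 1)]
        assert m.columns[j - 1] == (16193, 0)
        assert m.data[0, j] == "-" and m.data[1, j] == "C"

    def test_reference_rows_match_reference(self, reference):
        profiles = [HaplotypeProfile("s1", "p", HVS1, [])]
        m = build_aligned_matrix(profiles, reference, HVS1)
        assert "".join(m.data[0]) == reference.window_sequence(HVS1)
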