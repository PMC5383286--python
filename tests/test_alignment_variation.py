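"""Site classification, p-distances, NJ and monophyly checks."""

import math

import numpy as np
import pytest

import oracles
from mitocomp.alignment_variation import (Alignment, DistanceResult,
                                          check_monophyly, classify_sites,
                                          distance_table, nj_tree, p_distance)


def _random_alignment(rng, n=6, length=30, missing=0.05):
    chars = list("ACGT")
    rows = []
    for _ in range(n):
        row = rng.choice(chars, size=length)
        mask = rng.random(length) < missing
        row[mask] = rng.choice(["-", "N"], size=int(mask.sum()))
        rows.append("".join(row))
    return Alignment(labels=[f"s{i}" for i in range(n)], rows=rows)


class TestClassifySites:
    def test_singleton_definition(self):
        aln = Alignment(labels=list("abc"), rows=["AAA", "AAT", "AAT"])
        s = classify_sites(aln)
        assert (s.n_constant, s.n_singleton, s.n_parsimony_informative) == (2, 1, 0)

    def test_parsimony_informative_definition(self):
        aln = Alignment(labels=list("abcd"), rows=["AAT", "AAT", "AAC", "AAC"])
        s = classify_sites(aln)
        assert s.n_parsimony_informative == 1 and s.n_singleton == 0

    def test_complete_deletion_excludes_gap_columns(self):
        aln = Alignment(labels=list("ab"), rows=["A-C", "AAC"])
        s = classify_sites(aln)
        assert s.n_excluded == 1 and s.analyzed == 2

    def test_all_excluded_errors(self):
        aln = Alignment(labels=list("ab"), rows=["--", "AA"])
        with pytest.raises(ValueError):
            classify_sites(aln)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            aln = _random_alignment(rng)
            s = classify_sites(aln)
            const, single, pis, excl = oracles.classify(aln.rows)
            assert (s.n_constant, s.n_singleton,
                    s.n_parsimony_informative, s.n_excluded) == \
                   (const, single, pis, excl)
            assert s.n_variable == s.n_singleton + s.n_parsimony_informative


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(labels=list("ab"), rows=["ACGT", "ACGT"])
        assert p_distance(aln).matrix[0, 1] == 0.0

    def test_single_mismatch(self):
        aln = Alignment(labels=list("ab"), rows=["ACGT", "ACGA"])
        assert p_distance(aln).matrix[0, 1] == 0.25

    def test_pairwise_vs_complete_deletion(self):
        aln = Alignment(labels=list("ab"), rows=["AC-T", "ACGT"])
        comp = p_distance(aln, "complete")
        pair = p_distance(aln, "pairwise")
        assert comp.matrix[0, 1] == 0.0 == pair.matrix[0, 1]

    def test_no_comparable_sites_is_missing(self, caplog):
        aln = Alignment(labels=list("ab"), rows=["--AA", "AA--"])
        d = p_distance(aln, "pairwise")
        assert math.isnan(d.matrix[0, 1])

    def test_metric_on_gap_free_alignments(self, rng):
        for _ in range(20):
            aln = _random_alignment(rng, n=5, length=40, missing=0.0)
            m = p_distance(aln).matrix
            assert np.allclose(m, m.T) and np.all(np.diag(m) == 0)
            for i in range(5):
                for j in range(5):
                    for k in range(5):
                        assert m[i, j] <= m[i, k] + m[k, j] + 1e-12

    def test_average_is_upper_triangle_mean(self, rng):
        aln = _random_alignment(rng, n=4, length=50, missing=0.0)
        d = p_distance(aln)
        iu = np.triu_indices(4, 1)
        assert d.average == pytest.approx(float(d.matrix[iu].mean()))


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        labels = ["a", "b", "c"]
        mat = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        nwk = nj_tree(DistanceResult(labels=labels, matrix=mat))
        # a: (0.4+0.6-0.8)/2 = 0.1; b: 0.3; c: 0.5
        assert "a:0.1" in nwk and "b:0.3" in nwk and "c:0.5" in nwk

    def test_four_taxon_additive_recovery(self):
        # ((a:1,b:2):1,(c:3,d:4)) as an additive matrix
        labels = list("abcd")
        mat = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7],
                        [6, 7, 7, 0]], dtype=float)
        nwk = nj_tree(DistanceResult(labels=labels, matrix=mat))
        assert oracles.rf_distance(nwk, "((a:1,b:2):1,(c:3,d:4):0);") == 0

    def test_recovers_random_additive_trees(self, rng):
        for _ in range(10):
            nwk_true, labels, mat = oracles.random_additive_tree(rng, 8)
            nwk = nj_tree(DistanceResult(labels=labels, matrix=mat))
            assert oracles.rf_distance(nwk, nwk_true) == 0

    def test_missing_entries_error(self):
        mat = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceResult(labels=list("abc"), matrix=mat))

    def test_deterministic_rerun(self, rng):
        _, labels, mat = oracles.random_additive_tree(rng, 6)
        d = DistanceResult(labels=labels, matrix=mat)
        assert nj_tree(d) == nj_tree(d)


class TestMonophyly:
    def test_full_and_single_sets(self):
        nwk = "((a:1,b:1):1,(c:1,d:1):1);"
        assert check_monophyly(nwk, {"a", "b", "c", "d"})
        assert check_monophyly(nwk, {"c"})

    def test_clade_and_nonclade(self):
        nwk = "((a:1,b:1):1,(c:1,d:1):1);"
        assert check_monophyly(nwk, {"a", "b"})
        assert not check_monophyly(nwk, {"a", "c"})

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError):
            check_monophyly("((a:1,b:1):1,c:1);", {"z"})

    def test_agrees_with_bipartition_enumeration(self, rng):
        for _ in range(15):
            nwk, labels, _ = oracles.random_additive_tree(rng, 7)
            sides = oracles.bipartition_sides(nwk)
            pick = set(rng.choice(labels,
                                  size=int(rng.integers(1, 7)), replace=False))
            assert check_monophyly(nwk, pick) == (frozenset(pick) in sides)


def test_distance_table_layout(rng):
    aln = _random_alignment(rng, n=3, length=20, missing=0.0)
    d = p_distance(aln)
    lines = distance_table(d).strip().split("\n")
    assert lines[0] == "3" and len(lines) == 4
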