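"""Generator contracts: determinism, planted truth, recovery closure."""

import math

import numpy as np
import pytest

import mitocomp as mc
from mitocomp.alignment_variation import p_distance
from mitocomp.composition import base_composition, cohort_summary, skews
from mitocomp.genome_model import extract_feature_seq
from mitocomp.selection import gene_kaks
from mitocomp.synthetic_data import (GENE_ORDER, GeneEvolParams, SimConfig,
                                     TruthRecord, evolve_gene_alignment,
                                     generate_cohort, generate_mitogenome,
                                     random_tree)


class TestGenomeGeneration:
    def test_vertebrate_gene_order_and_strands(self, default_sim):
        genome, annotation, _ = default_sim
        assert [f.name for f in annotation.features] == [n for n, _, _ in GENE_ORDER]
        assert annotation.get("ND6").strand == "L"
        light = {f.name for f in annotation.features if f.strand == "L"}
        assert len(light & {f.name for f in annotation.by_kind("tRNA")}) == 8
        assert len(annotation.features) == 38

    def test_seed_determinism(self):
        g1, a1, t1 = generate_mitogenome(SimConfig(seed=42))
        g2, a2, t2 = generate_mitogenome(SimConfig(seed=42))
        assert g1.sequence == g2.sequence
        assert t1.values == t2.values
        g3, _, _ = generate_mitogenome(SimConfig(seed=43))
        assert g3.sequence != g1.sequence

    def test_composition_targets_hit_for_large_regions(self, default_sim):
        genome, annotation, _ = default_sim
        cfg = SimConfig()
        for feat in annotation.features:
            if feat.kind == "tRNA" or feat.length_on(genome.length) < 300:
                continue
            seq = extract_feature_seq(genome, feat)
            target = cfg.composition.get(feat.name, cfg.composition["default"])
            c = base_composition(seq)
            for got, want in zip((c.pct_A, c.pct_C, c.pct_G, c.pct_T), target):
                assert abs(got - want) <= 1.5, feat.name

    def test_planted_skew_signs(self, default_sim):
        genome, annotation, truth = default_sim
        s = skews(base_composition(genome.sequence))
        assert np.sign(s.at_skew) == truth.values["comp.default.at_skew_sign"]
        assert np.sign(s.gc_skew) == truth.values["comp.default.gc_skew_sign"]

    def test_infeasible_overlap_errors(self):
        cfg = SimConfig(overlaps=(("ATP8", "ATP6", 500),))
        with pytest.raises(ValueError, match="longer"):
            generate_mitogenome(cfg)

    def test_truth_round_trips_through_file(self, default_sim, tmp_path):
        _, _, truth = default_sim
        truth.write(tmp_path / "truth.tsv")
        back = TruthRecord.read(tmp_path / "truth.tsv")
        assert set(back.values) == set(truth.values)
        assert back.values["codon.COI.start"] == "GTG"


class TestEvolver:
    def test_zero_branch_lengths_identity(self):
        tree = "((a:0.0,b:0.0):0.0,c:0.0);"
        aln, _ = evolve_gene_alignment(GeneEvolParams(tree=tree, n_codons=50,
                                                      seed=1))
        assert p_distance(aln).average == 0.0

    def test_omega_zero_forbids_nonsynonymous_change(self):
        """omega = 0 keeps every protein identical.  The NG86 estimate of Ka
        is then near zero but not exactly zero: pathway averaging over
        multi-hit codons attributes a fraction of purely synonymous double
        hits to nonsynonymous paths (e.g. CTC->TTA via the Phe intermediate),
        which is a property of the estimator, not of the simulated history."""
        from mitocomp.codon_usage import translate_mt
        tree = "((a:0.3,b:0.3):0.1,c:0.3);"
        aln, _ = evolve_gene_alignment(GeneEvolParams(tree=tree, omega=0.0,
                                                      n_codons=300, seed=2))
        proteins = {translate_mt(row) for row in aln.rows}
        assert len(proteins) == 1
        r = gene_kaks(aln)
        assert r.Ks > 0.0 and r.Ka < 0.01 * r.Ks + 1e-3

    def test_seed_determinism(self):
        tree = "((a:0.1,b:0.1):0.05,c:0.1);"
        p = GeneEvolParams(tree=tree, n_codons=100, seed=9)
        a1, _ = evolve_gene_alignment(p)
        a2, _ = evolve_gene_alignment(p)
        assert a1.rows == a2.rows

    def test_frozen_codons_never_change(self):
        tree = "((a:0.5,b:0.5):0.2,c:0.5);"
        p = GeneEvolParams(tree=tree, n_codons=60, seed=4,
                           frozen_codons=(0, 59))
        aln, _ = evolve_gene_alignment(p)
        firsts = {r[:3] for r in aln.rows}
        lasts = {r[-3:] for r in aln.rows}
        assert len(firsts) == 1 and len(lasts) == 1

    def test_no_stop_codons_ever(self):
        from mitocomp.codon_usage import STOP_CODONS
        tree = "((a:0.4,b:0.4):0.2,c:0.4);"
        aln, _ = evolve_gene_alignment(GeneEvolParams(tree=tree, omega=1.0,
                                                      n_codons=200, seed=5))
        for row in aln.rows:
            for i in range(0, len(row), 3):
                assert row[i:i + 3] not in STOP_CODONS

    def test_zero_codons_errors(self):
        with pytest.raises(ValueError):
            evolve_gene_alignment(GeneEvolParams(tree="(a:1,b:1);", n_codons=0))


class TestCohort:
    def test_files_written_and_reloadable(self, tmp_path):
        from mitocomp.genome_model import load_genome
        generate_cohort(3, SimConfig(seed=5), out_dir=tmp_path)
        fastas = sorted(tmp_path.glob("taxon*.fasta"))
        assert len(fastas) == 3
        g, ann = load_genome(fastas[0], str(fastas[0])[:-6] + ".features.tsv")
        assert len(ann.features) == 38
        assert (tmp_path / "alignments" / "COI.fasta").exists()
        assert (tmp_path / "truth.tsv").exists()

    def test_sizes_match_truth(self, small_cohort):
        genomes, _, truth = small_cohort
        for genome, _ in genomes:
            assert genome.length == int(truth.values[f"{genome.id}.size"])
        stats = cohort_summary([g.length for g, _ in genomes])
        assert stats.min <= stats.mean <= stats.max

    def test_alignments_are_orthologous_and_divergent(self, small_cohort):
        genomes, alignments, _ = small_cohort
        assert set(alignments) == {g for g, k, _ in GENE_ORDER if k == "PCG"}
        d = p_distance(alignments["COI"]).average
        assert 0.0 < d < 0.5

    def test_genome_pcg_matches_alignment_row(self, small_cohort):
        from mitocomp.codon_usage import excise_inserts
        genomes, alignments, _ = small_cohort
        genome, annotation = genomes[0]
        for gene in ("COI", "ND6", "ND3"):
            feat = annotation.get(gene)
            seq = excise_inserts(extract_feature_seq(genome, feat),
                                 feat.frameshift_inserts)
            row = dict(zip(alignments[gene].labels,
                           alignments[gene].rows))[genome.id]
            assert seq.startswith(row)

    def test_needs_two_taxa(self):
        with pytest.raises(ValueError):
            generate_cohort(1)


def test_random_tree_is_parsable_with_all_labels(rng):
    import dendropy
    labels = [f"x{i}" for i in range(9)]
    tree = dendropy.Tree.get(data=random_tree(labels, rng), schema="newick")
    assert {l.taxon.label for l in tree.leaf_node_iter()} == set(labels)
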