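"""Genome parsing, coordinate conventions and layout accounting."""

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

import mitocomp as mc
from mitocomp.genome_model import (GeneFeature, GenomeAnnotation,
                                   extract_feature_seq, gene_layout,
                                   load_genome, parse_genbank_record, revcomp,
                                   write_annotation_table, write_fasta,
                                   write_feature_table)


def _genbank_text(genome, annotation):
    """Render one of our genomes as a GenBank flat file via Biopython."""
    rec = SeqRecord(Seq(genome.sequence), id="SYN000001", name="SYN000001",
                    description="synthetic mitochondrial genome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    for f in annotation.features:
        ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                 "CR": "D-loop"}[f.kind]
        loc = SimpleLocation(f.start, f.end,
                             strand=-1 if f.strand == "L" else 1)
        feat = SeqFeature(loc, type=ftype)
        if f.kind != "CR":
            feat.qualifiers["gene"] = [f.name]
        rec.features.append(feat)
    return rec.format("genbank")


class TestGenBankParsing:
    def test_round_trip_preserves_coordinates_strands_names(self, default_sim):
        genome, annotation, _ = default_sim
        parsed_g, parsed_ann = parse_genbank_record(
            _genbank_text(genome, annotation))
        assert parsed_g.sequence == genome.sequence
        got = {f.name: (f.start, f.end, f.strand) for f in parsed_ann.features}
        want = {f.name: (f.start, f.end, f.strand) for f in annotation.features}
        assert got == want

    def test_light_strand_cds_maps_to_strand_L(self, default_sim):
        genome, annotation, _ = default_sim
        _, parsed = parse_genbank_record(_genbank_text(genome, annotation))
        assert parsed.get("ND6").strand == "L"
        assert sum(1 for f in parsed.features if f.strand == "L") == 9

    def test_synonym_normalization(self):
        rec = SeqRecord(Seq("ATG" * 200), id="X1", name="X1", description="")
        rec.annotations["molecule_type"] = "DNA"
        cds = SeqFeature(SimpleLocation(0, 30, strand=1), type="CDS")
        cds.qualifiers["gene"] = ["COX1"]
        rec.features = [cds,
                        SeqFeature(SimpleLocation(30, 90, strand=1), type="D-loop")]
        _, ann = parse_genbank_record(rec.format("genbank"))
        assert {f.name for f in ann.features} == {"COI", "CR"}
        # GenBank 1..30 is internal (0, 30)
        assert (ann.get("COI").start, ann.get("COI").end) == (0, 30)

    def test_unmappable_name_kept_with_warning(self):
        rec = SeqRecord(Seq("ACGT" * 100), id="X2", name="X2", description="")
        rec.annotations["molecule_type"] = "DNA"
        odd = SeqFeature(SimpleLocation(0, 30, strand=1), type="CDS")
        odd.qualifiers["gene"] = ["ORF-weird"]
        rec.features = [odd,
                        SeqFeature(SimpleLocation(40, 90, strand=1), type="D-loop")]
        with pytest.warns(UserWarning, match="not in canonical"):
            _, ann = parse_genbank_record(rec.format("genbank"))
        assert not ann.get("ORF-weird").canonical


class TestFeatureTableIO:
    def test_fasta_table_round_trip(self, default_sim, tmp_path):
        genome, annotation, _ = default_sim
        write_fasta(genome, tmp_path / "g.fasta")
        write_feature_table(annotation, tmp_path / "g.features.tsv")
        g2, ann2 = load_genome(tmp_path / "g.fasta", tmp_path / "g.features.tsv")
        assert g2.sequence == genome.sequence
        assert [(f.name, f.start, f.end, f.strand, f.frameshift_inserts)
                for f in ann2.features] == \
               [(f.name, f.start, f.end, f.strand, f.frameshift_inserts)
                for f in annotation.features]

    def test_one_based_convention(self, tmp_path):
        (tmp_path / "g.fasta").write_text(">g\n" + "A" * 16899 + "\n")
        (tmp_path / "g.features.tsv").write_text(
            "name\tkind\tstart\tend\tstrand\nCR\tCR\t15500\t16899\tH\n")
        _, ann = load_genome(tmp_path / "g.fasta", tmp_path / "g.features.tsv")
        assert (ann.get("CR").start, ann.get("CR").end) == (15499, 16899)

    def test_out_of_range_coordinates_error(self, tmp_path):
        (tmp_path / "g.fasta").write_text(">g\n" + "A" * 100 + "\n")
        (tmp_path / "g.features.tsv").write_text(
            "name\tkind\tstart\tend\tstrand\nCR\tCR\t50\t200\tH\n")
        with pytest.raises(ValueError, match="outside genome"):
            load_genome(tmp_path / "g.fasta", tmp_path / "g.features.tsv")

    def test_duplicate_names_error(self):
        feats = [GeneFeature("CR", "CR", 0, 10), GeneFeature("CR", "CR", 20, 30)]
        with pytest.raises(ValueError, match="exactly one CR|duplicate"):
            GenomeAnnotation(features=feats)


class TestExtraction:
    def test_reverse_complement_extraction(self):
        g = mc.MitoGenome(id="g", sequence="AAACCCGGGTTT")
        f = GeneFeature("ND6", "PCG", 0, 6, strand="L")
        assert extract_feature_seq(g, f) == "GGGTTT"

    def test_revcomp_is_involution_with_strand_flip(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        assert revcomp(revcomp(seq)) == seq

    def test_wrapped_feature_spans_origin(self):
        g = mc.MitoGenome(id="g", sequence="AAACCCGGGTTT")
        f = GeneFeature("CR", "CR", 9, 3, wrapped=True)
        assert extract_feature_seq(g, f) == "TTTAAA"
        assert f.length_on(g.length) == 6

    def test_planted_atp8_length(self, default_sim):
        genome, annotation, _ = default_sim
        assert len(extract_feature_seq(genome, annotation.get("ATP8"))) == 168


class TestLayout:
    def test_simple_overlap_gap(self):
        g = mc.MitoGenome(id="g", sequence="A" * 30)
        ann = GenomeAnnotation(features=[
            GeneFeature("ND1", "PCG", 0, 10), GeneFeature("CR", "CR", 5, 20)])
        layout = gene_layout(ann, g)
        assert ("ND1", "CR", -5) in layout.adjacencies
        assert layout.n_overlaps == 1 and layout.total_overlap_bp == 5

    def test_default_genome_longest_overlap_is_atp8_atp6(self, default_sim):
        genome, annotation, _ = default_sim
        layout = gene_layout(annotation, genome)
        gaps = {(u, d): g for u, d, g in layout.adjacencies}
        assert gaps[("ATP8", "ATP6")] == -10
        assert min(gaps.values()) == -10

    def test_circular_conservation(self, rng):
        """Spacer total equals genome length minus covered length when no
        features overlap (the circular junction included)."""
        L = 500
        cuts = np.sort(rng.choice(np.arange(1, L), size=12, replace=False))
        bounds = [0] + list(map(int, cuts)) + [L]
        feats = []
        covered = 0
        for k in range(0, len(bounds) - 1, 2):
            s, e = bounds[k], bounds[k + 1]
            if e <= s:
                continue
            kind = "CR" if not feats else "tRNA"
            feats.append(GeneFeature(f"f{k}" if feats else "CR", kind, s, e))
            covered += e - s
        g = mc.MitoGenome(id="g", sequence="A" * L)
        layout = gene_layout(GenomeAnnotation(features=feats), g)
        assert layout.total_overlap_bp == 0
        assert layout.total_spacer_bp == L - covered

    def test_annotation_table_header_and_rows(self, default_sim):
        genome, annotation, _ = default_sim
        layout = gene_layout(annotation, genome)
        table = write_annotation_table(annotation, layout, genome)
        lines = table.strip().split("\n")
        assert lines[0] == "name\tkind\tstart\tend\tstrand\tsize\tgap_to_next"
        assert len(lines) == len(annotation.features) + 1
        # re-derive 1-based starts
        first = lines[1].split("\t")
        assert int(first[2]) == annotation.features[0].start + 1
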