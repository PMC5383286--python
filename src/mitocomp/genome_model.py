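"""Annotated mitochondrial genomes: parsing, coordinates, and gene layout.

A vertebrate mitogenome is a circular molecule of ~16-17 kb carrying 13
protein-coding genes (PCGs), 22 tRNAs, two rRNAs and one non-coding control
region (CR).  This module defines the in-memory representation used by every
downstream analysis — :class:`MitoGenome` plus a strand-aware
:class:`GenomeAnnotation` — together with readers for GenBank flat files and
the package's own FASTA + feature-table dialect, and the genome-organization
report (gene overlaps and intergenic spacers).

Coordinate conventions
----------------------
Internally every feature is 0-based, half-open on the reference (heavy)
strand.  All file formats read and written here are 1-based inclusive, the
GenBank convention.  A feature that spans the origin of the circular molecule
is stored with ``wrapped=True`` and ``end < start``; its sequence is the
concatenation of the two arcs.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger("mitocomp")

# ---------------------------------------------------------------------------
# Canonical region vocabulary
# ---------------------------------------------------------------------------

PCG_NAMES = (
    "ND1", "ND2", "COI", "COII", "ATP8", "ATP6", "COIII",
    "ND3", "ND4L", "ND4", "ND5", "CYTB", "ND6",
)
RRNA_NAMES = ("12S", "16S")
TRNA_NAMES = (
    "tRNA-Phe", "tRNA-Val", "tRNA-Leu(UUR)", "tRNA-Ile", "tRNA-Gln",
    "tRNA-Met", "tRNA-Trp", "tRNA-Ala", "tRNA-Asn", "tRNA-Cys", "tRNA-Tyr",
    "tRNA-Ser(UCN)", "tRNA-Asp", "tRNA-Lys", "tRNA-Gly", "tRNA-Arg",
    "tRNA-His", "tRNA-Ser(AGY)", "tRNA-Leu(CUN)", "tRNA-Glu", "tRNA-Thr",
    "tRNA-Pro",
)
CANONICAL_NAMES = PCG_NAMES + RRNA_NAMES + TRNA_NAMES + ("CR",)

#: Synonyms seen in GenBank annotations, mapped to the canonical vocabulary.
#: tRNA isoacceptors (two Leu, two Ser) are disambiguated positionally by the
#: parser, so the bare names map to a placeholder resolved later.
SYNONYMS = {
    "COX1": "COI", "COX2": "COII", "COX3": "COIII",
    "CO1": "COI", "CO2": "COII", "CO3": "COIII",
    "COXI": "COI", "COXII": "COII", "COXIII": "COIII",
    "CYTOCHROME B": "CYTB", "COB": "CYTB", "CYT B": "CYTB", "CYB": "CYTB",
    "ATPASE8": "ATP8", "ATPASE6": "ATP6", "ATP SYNTHASE F0 SUBUNIT 8": "ATP8",
    "ATP SYNTHASE F0 SUBUNIT 6": "ATP6",
    "D-LOOP": "CR", "CONTROL REGION": "CR", "D LOOP": "CR",
    "12S RRNA": "12S", "16S RRNA": "16S",
    "12S RIBOSOMAL RNA": "12S", "16S RIBOSOMAL RNA": "16S",
    "S-RRNA": "12S", "L-RRNA": "16S", "RRNS": "12S", "RRNL": "16S",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MitoGenome:
    """One circular mitochondrial sequence with identity metadata."""

    id: str
    sequence: str
    accession: str = ""
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id}: disallowed characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A strand-aware region on the reference (heavy) strand.

    ``start``/``end`` are 0-based half-open.  A feature with ``wrapped=True``
    spans the origin and has ``end < start``.  ``frameshift_inserts`` lists
    gene-relative 1-based positions of single-nucleotide insertions that are
    excised before translation (e.g. the extra C seen in many shorebird ND3
    genes, which has no coding significance).
    """

    name: str
    kind: str  # one of PCG / tRNA / rRNA / CR
    start: int
    end: int
    strand: str = "H"
    wrapped: bool = False
    frameshift_inserts: tuple[int, ...] = ()
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("PCG", "tRNA", "rRNA", "CR"):
            raise ValueError(f"{self.name}: unknown feature kind {self.kind!r}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"{self.name}: strand must be H or L")
        if not self.wrapped and not self.start < self.end:
            raise ValueError(f"{self.name}: empty or inverted span {self.start}..{self.end}")

    def length_on(self, genome_length: int) -> int:
        if self.wrapped:
            return (genome_length - self.start) + self.end
        return self.end - self.start

    def incomplete_stop_candidate(self) -> bool:
        """True when the coding length is not a codon multiple (PCG only)."""
        if self.kind != "PCG":
            return False
        n = self.end - self.start - len(self.frameshift_inserts)
        return n % 3 in (1, 2)


@dataclass
class GenomeAnnotation:
    """Ordered feature list for one genome; exactly one CR, unique names."""

    features: list[GeneFeature]
    genome_id: str = ""

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        n_cr = sum(1 for f in self.features if f.kind == "CR")
        if n_cr != 1:
            raise ValueError(f"annotation must contain exactly one CR, found {n_cr}")

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]


@dataclass
class LayoutReport:
    """Adjacency gaps around the circle: negative = overlap, positive = spacer."""

    adjacencies: list[tuple[str, str, int]]
    n_overlaps: int = field(init=False)
    total_overlap_bp: int = field(init=False)
    n_spacers: int = field(init=False)
    total_spacer_bp: int = field(init=False)

    def __post_init__(self) -> None:
        gaps = [g for _, _, g in self.adjacencies]
        self.n_overlaps = sum(1 for g in gaps if g < 0)
        self.total_overlap_bp = -sum(g for g in gaps if g < 0)
        self.n_spacers = sum(1 for g in gaps if g > 0)
        self.total_spacer_bp = sum(g for g in gaps if g > 0)


# ---------------------------------------------------------------------------
# GenBank parsing
# ---------------------------------------------------------------------------

def _normalize_name(raw: str) -> tuple[str, bool]:
    """Map a raw feature name onto the canonical vocabulary.

    Returns (name, canonical?).  Unmappable names are kept verbatim and
    flagged non-canonical with a warning, so odd records still load.
    """
    key = raw.strip().upper()
    if key in SYNONYMS:
        return SYNONYMS[key], True
    for cand in CANONICAL_NAMES:
        if key == cand.upper():
            return cand, True
    # bare tRNA names ("tRNA-Leu") are resolved positionally by the caller
    if key.startswith("TRNA-"):
        aa = key[5:].split("(")[0].capitalize()
        suffix = key[5 + len(aa):]
        name = f"tRNA-{aa}{suffix}" if suffix else f"tRNA-{aa}"
        if name in TRNA_NAMES or name in ("tRNA-Leu", "tRNA-Ser"):
            return name, True
    warnings.warn(f"feature name {raw!r} not in canonical vocabulary; kept as-is")
    return raw, False


def _resolve_isoacceptors(features: list[GeneFeature]) -> None:
    """Disambiguate the two Leu and two Ser tRNAs by genomic order.

    In the conserved vertebrate arrangement Leu(UUR) precedes Leu(CUN) and
    Ser(UCN) precedes Ser(AGY) on the reference strand, so first occurrence
    wins the first label.
    """
    order = {"tRNA-Leu": ["tRNA-Leu(UUR)", "tRNA-Leu(CUN)"],
             "tRNA-Ser": ["tRNA-Ser(UCN)", "tRNA-Ser(AGY)"]}
    seen: dict[str, int] = {}
    for f in features:
        if f.name in order:
            idx = seen.get(f.name, 0)
            seen[f.name] = idx + 1
            if idx < 2:
                f.name = order[f.name][idx]


def parse_genbank_record(record_text: str) -> tuple[MitoGenome, GenomeAnnotation]:
    """Parse one GenBank flat-file record into (genome, annotation).

    Coordinates are converted from GenBank 1-based inclusive to internal
    0-based half-open; complement-strand features become strand L; names are
    normalized through the synonym map (``D-loop`` -> ``CR``, ``COX1`` ->
    ``COI``, ...).  A record without sequence is a hard error; features whose
    names cannot be mapped are kept verbatim and flagged non-canonical.
    """
    record = SeqIO.read(io.StringIO(record_text), "genbank")
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise ValueError(f"record {record.id}: missing sequence")
    genome = MitoGenome(id=record.id, accession=record.id, sequence=seq)

    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type == "CDS" or feat.type == "gene":
            kind = "PCG"
        elif feat.type == "tRNA":
            kind = "tRNA"
        elif feat.type == "rRNA":
            kind = "rRNA"
        elif feat.type in ("D-loop", "misc_feature"):
            kind = "CR"
        else:
            continue
        raw = (feat.qualifiers.get("gene") or feat.qualifiers.get("product")
               or [feat.type])[0]
        if feat.type == "D-loop":
            raw = "CR"
        name, canonical = _normalize_name(raw)
        if kind == "PCG" and name not in PCG_NAMES and feat.type == "gene":
            continue  # gene features duplicating tRNA/rRNA spans
        if name == "CR":
            kind = "CR"
        elif canonical and name in RRNA_NAMES:
            kind = "rRNA"
        elif canonical and name.startswith("tRNA"):
            kind = "tRNA"
        loc = feat.location
        strand = "L" if loc.strand == -1 else "H"
        start, end = int(loc.start), int(loc.end)
        wrapped = False
        if len(loc.parts) > 1:  # origin-spanning join
            p0, p1 = loc.parts[0], loc.parts[-1]
            start, end = int(p0.start), int(p1.end)
            wrapped = end < start
        if any(f.name == name for f in features):
            continue  # CDS repeated as gene feature etc.
        features.append(GeneFeature(name=name, kind=kind, start=start, end=end,
                                    strand=strand, wrapped=wrapped,
                                    canonical=canonical))
    if not features:
        raise ValueError(f"record {record.id}: no usable features")
    _resolve_isoacceptors(features)
    features.sort(key=lambda f: f.start)
    return genome, GenomeAnnotation(features=features, genome_id=genome.id)


# ---------------------------------------------------------------------------
# FASTA + feature-table dialect
# ---------------------------------------------------------------------------

FEATURE_TABLE_HEADER = ("name", "kind", "start", "end", "strand",
                        "wrapped", "frameshift_inserts")


def write_fasta(genome: MitoGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id} {genome.accession}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i:i + 70] + "\n")


def read_fasta(path) -> MitoGenome:
    record = SeqIO.read(str(path), "fasta")
    parts = record.description.split(maxsplit=1)
    accession = parts[1] if len(parts) > 1 else ""
    return MitoGenome(id=record.id, accession=accession,
                      sequence=str(record.seq))


def write_feature_table(annotation: GenomeAnnotation, path) -> None:
    """Write the tab-separated feature table (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("\t".join(FEATURE_TABLE_HEADER) + "\n")
        for f in annotation.features:
            inserts = ",".join(str(i) for i in f.frameshift_inserts)
            fh.write(f"{f.name}\t{f.kind}\t{f.start + 1}\t{f.end}\t{f.strand}"
                     f"\t{int(f.wrapped)}\t{inserts}\n")


def load_genome(fasta_path, feature_table_path) -> tuple[MitoGenome, GenomeAnnotation]:
    """Load a genome from FASTA plus the package's tab-separated feature table.

    The table carries 1-based inclusive coordinates (columns: name, kind,
    start, end, strand[, wrapped, frameshift_inserts]); they are converted to
    the internal 0-based half-open convention.  Coordinates outside the
    sequence on a non-wrapped feature are an error.
    """
    genome = read_fasta(fasta_path)
    features: list[GeneFeature] = []
    with open(feature_table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            start1, end1 = int(row["start"]), int(row["end"])
            wrapped = bool(int(row.get("wrapped", "0") or "0"))
            inserts = tuple(int(x) for x in row.get("frameshift_inserts", "").split(",")
                            if x.strip())
            start, end = start1 - 1, end1
            if not wrapped and (start < 0 or end > genome.length or start >= end):
                raise ValueError(
                    f"{feature_table_path} line {lineno}: coordinates "
                    f"{start1}..{end1} outside genome of {genome.length} bp")
            features.append(GeneFeature(name=row["name"], kind=row["kind"],
                                        start=start, end=end,
                                        strand=row["strand"], wrapped=wrapped,
                                        frameshift_inserts=inserts))
    features.sort(key=lambda f: f.start)
    return genome, GenomeAnnotation(features=features, genome_id=genome.id)


# ---------------------------------------------------------------------------
# Sequence extraction and layout statistics
# ---------------------------------------------------------------------------

def extract_feature_seq(genome: MitoGenome, feature: GeneFeature) -> str:
    """Region sequence in coding sense: reference slice for strand H,
    reverse complement for strand L; wrapped features join the two arcs."""
    if feature.wrapped:
        raw = genome.sequence[feature.start:] + genome.sequence[:feature.end]
    else:
        raw = genome.sequence[feature.start:feature.end]
    return revcomp(raw) if feature.strand == "L" else raw


def gene_layout(annotation: GenomeAnnotation, genome: MitoGenome) -> LayoutReport:
    """Gap between every adjacent feature pair around the circle.

    Gaps are computed on reference-strand coordinates regardless of coding
    strand (overlap counts in the literature mix strands, e.g. adjacent tRNAs
    on opposite strands).  Negative gap = overlap, positive = spacer; the
    circular junction between the last and first feature is included.
    """
    feats = list(annotation.features)
    if feats != sorted(feats, key=lambda f: f.start):
        logger.warning("features unordered; sorting by start")
        feats.sort(key=lambda f: f.start)
    L = genome.length
    adjacencies: list[tuple[str, str, int]] = []
    for prev, nxt in zip(feats, feats[1:]):
        prev_end = prev.end + L if prev.wrapped else prev.end
        adjacencies.append((prev.name, nxt.name, nxt.start - prev_end))
    last, first = feats[-1], feats[0]
    last_end = last.end if last.wrapped else last.end - L
    adjacencies.append((last.name, first.name, first.start - last_end))
    return LayoutReport(adjacencies=adjacencies)


def write_annotation_table(annotation: GenomeAnnotation, layout: LayoutReport,
                           genome: MitoGenome) -> str:
    """Per-feature report (1-based coordinates, size, gap to next feature)."""
    gap_after = {up: gap for up, _, gap in layout.adjacencies}
    lines = ["name\tkind\tstart\tend\tstrand\tsize\tgap_to_next"]
    for f in annotation.features:
        lines.append(f"{f.name}\t{f.kind}\t{f.start + 1}\t{f.end}\t{f.strand}"
                     f"\t{f.length_on(genome.length)}\t{gap_after.get(f.name, 0)}")
    return "\n".join(lines) + "\n"
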