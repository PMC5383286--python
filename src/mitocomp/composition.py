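"""Nucleotide composition, AT/GC content and strand-skew statistics.

Mitochondrial strands are compositionally asymmetric; the standard summary
statistics are

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed on the reference (heavy) strand or, for protein-coding genes, on the
coding strand.  Avian mitogenomes typically show positive AT skew and
strongly negative GC skew genome-wide.  This module computes per-sequence and
per-region composition rows, cohort-level summaries (mean, population SD,
labeled extrema), and the tab-separated reports that mirror the usual
published composition tables.

The bundled table ``data/charadriiformes_published.tsv`` carries the
published genome sizes and whole-genome composition columns for a 20-species
shorebird (Charadriiformes) cohort, used as reference input for cohort
summaries when the underlying GenBank records are not at hand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .genome_model import (GeneFeature, GenomeAnnotation, MitoGenome,
                           extract_feature_seq, revcomp)

WHOLE_GENOME = "WHOLE_GENOME"


@dataclass
class Composition:
    """Exact base counts of one sequence; N and other IUPAC codes are
    tallied under ``other`` and count toward ``total`` but not toward the
    A/C/G/T percentages."""

    A: int
    C: int
    G: int
    T: int
    other: int = 0
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.A + self.C + self.G + self.T + self.other

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.total if self.total else float("nan")

    @property
    def pct_A(self) -> float:
        return self._pct(self.A)

    @property
    def pct_C(self) -> float:
        return self._pct(self.C)

    @property
    def pct_G(self) -> float:
        return self._pct(self.G)

    @property
    def pct_T(self) -> float:
        return self._pct(self.T)

    @property
    def at_content(self) -> float:
        return self.pct_A + self.pct_T


@dataclass
class SkewPair:
    at_skew: float
    gc_skew: float

    def defined(self) -> bool:
        return not (math.isnan(self.at_skew) or math.isnan(self.gc_skew))


@dataclass
class CompositionRow:
    species: str
    accession: str
    region: str
    composition: Composition
    skews: SkewPair

    @property
    def at_content(self) -> float:
        return self.composition.at_content


@dataclass
class CohortStats:
    """Cohort summary: mean, population SD (divisor n), labeled extrema."""

    n: int
    mean: float
    sd: float
    min: float
    argmin: str
    max: float
    argmax: str


def base_composition(seq: str) -> Composition:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    return Composition(A=a, C=c, G=g, T=t, other=len(s) - a - c - g - t)


def skews(comp: Composition) -> SkewPair:
    """Apply the skew formulas; a zero denominator yields NaN, not an error."""
    at = (comp.A - comp.T) / (comp.A + comp.T) if comp.A + comp.T else float("nan")
    gc = (comp.G - comp.C) / (comp.G + comp.C) if comp.G + comp.C else float("nan")
    return SkewPair(at_skew=at, gc_skew=gc)


def composition_row(seq: str, species: str, accession: str = "",
                    region: str = WHOLE_GENOME) -> CompositionRow:
    comp = base_composition(seq)
    return CompositionRow(species=species, accession=accession, region=region,
                          composition=comp, skews=skews(comp))


def region_profiles(genome: MitoGenome, annotation: GenomeAnnotation,
                    coding_sense: bool = True) -> list[CompositionRow]:
    """One CompositionRow per PCG, per rRNA, the CR, and the whole genome.

    PCG sequences are taken on the coding strand by default so that skews of
    the single light-strand gene (ND6) are reported in its own reading sense;
    ``coding_sense=False`` reports every region on the reference strand
    instead.
    """
    rows = [composition_row(genome.sequence, genome.id, genome.accession)]
    for feat in annotation.features:
        if feat.kind not in ("PCG", "rRNA", "CR"):
            continue
        seq = extract_feature_seq(genome, feat)
        if not coding_sense and feat.strand == "L":
            seq = revcomp(seq)
        rows.append(composition_row(seq, genome.id, genome.accession, feat.name))
    return rows


def cohort_summary(values, labels=None) -> CohortStats:
    """Mean, population SD (divisor n) and labeled extrema of one column.

    The population form of the SD is used throughout the package: the
    published cohort dispersion (SD 179.66 for the 20 genome sizes) is the
    divisor-n value, not the sample estimate.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("cohort_summary needs at least one value")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(vals))]
    n = len(vals)
    mean = sum(vals) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / n)
    imin = min(range(n), key=lambda i: vals[i])
    imax = max(range(n), key=lambda i: vals[i])
    return CohortStats(n=n, mean=mean, sd=sd, min=vals[imin], argmin=labels[imin],
                       max=vals[imax], argmax=labels[imax])


# ---------------------------------------------------------------------------
# Reports and the published reference table
# ---------------------------------------------------------------------------

def composition_table(rows: list[CompositionRow], ndigits: int = 2) -> str:
    """Whole-genome composition report, one species per row."""
    lines = ["species\taccession\tA\tT\tG\tC\tat_content\tat_skew\tgc_skew"]
    for r in rows:
        c = r.composition
        lines.append("\t".join([r.species, r.accession] + [
            f"{v:.{ndigits}f}" for v in (c.pct_A, c.pct_T, c.pct_G, c.pct_C,
                                         c.at_content, r.skews.at_skew,
                                         r.skews.gc_skew)]))
    return "\n".join(lines) + "\n"


def region_table(rows: list[CompositionRow], ndigits: int = 2) -> str:
    """Long-format per-region table (species, region, AT content, skews)."""
    lines = ["species\taccession\tregion\tat_content\tat_skew\tgc_skew"]
    for r in rows:
        lines.append("\t".join([r.species, r.accession, r.region,
                                f"{r.at_content:.{ndigits}f}",
                                f"{r.skews.at_skew:.{ndigits}f}",
                                f"{r.skews.gc_skew:.{ndigits}f}"]))
    return "\n".join(lines) + "\n"


def load_published_cohort() -> pd.DataFrame:
    """The published 20-genome shorebird cohort table (sizes, whole-genome
    composition percentages and skews), as a DataFrame."""
    path = resources.files("mitocomp") / "data" / "charadriiformes_published.tsv"
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")
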