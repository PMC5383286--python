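"""Vertebrate mitochondrial genetic code, start/stop detection, codon usage.

The vertebrate mitochondrial code differs from the universal code in three
ways that matter for annotation: AGA/AGG are stop codons, TGA encodes Trp,
and ATA encodes Met.  Mitochondrial genes also start on a wider candidate
set (ATG, GTG, ATT, ATC, ATA) and frequently end on an incomplete stop — a
terminal T or TA completed to TAA by post-transcriptional polyadenylation of
the mRNA.  A further quirk handled here is the single-nucleotide insertion
seen in ND3 of many birds and turtles: it is excised before framing, as it is
not translated.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .alignment_variation import Alignment

_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial

#: codon -> one-letter amino acid, with '*' for the four stops.
MITO_CODE: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    MITO_CODE[_stop] = "*"

STOP_CODONS = frozenset(_TABLE.stop_codons)          # TAA TAG AGA AGG
START_CODONS = frozenset({"ATG", "GTG", "ATT", "ATC", "ATA"})

assert len(MITO_CODE) == 64 and len(STOP_CODONS) == 4


@dataclass
class CodonReport:
    """Start/stop assignment for one gene in one genome."""

    gene: str
    species: str
    start_codon: str
    stop_codon: str          # 3-mer, or "TA-"/"T--" when incomplete
    complete_stop: bool
    nonstandard_start: bool = False
    internal_stop: bool = False


def excise_inserts(seq: str, inserts) -> str:
    """Remove single-nucleotide insertions at gene-relative 1-based positions."""
    if not inserts:
        return seq
    drop = set(inserts)
    return "".join(c for i, c in enumerate(seq, start=1) if i not in drop)


def translate_mt(seq: str, frame_offset: int = 0) -> str:
    """Translate under the vertebrate mitochondrial code, halting at the
    first stop codon (or at the end of the last complete codon)."""
    s = seq[frame_offset:].upper()
    out = []
    for i in range(0, len(s) - 2, 3):
        aa = MITO_CODE.get(s[i:i + 3])
        if aa is None:  # ambiguous codon
            out.append("X")
            continue
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def has_internal_stop(seq: str) -> bool:
    """True if any codon before the final one is a stop (after framing)."""
    s = seq.upper()
    n_codons = len(s) // 3
    return any(s[3 * i:3 * i + 3] in STOP_CODONS for i in range(n_codons - 1))


def start_stop_codons(gene_seq: str, frameshift_inserts=(), gene: str = "",
                      species: str = "") -> CodonReport:
    """Classify the start and stop codon of one coding-sense gene sequence.

    Frameshift insertions are excised first.  The stop is the final complete
    codon when the coding length is a codon multiple; a trailing T or TA is
    reported as the incomplete classes "T--" / "TA-" (completed to TAA on the
    mature transcript).  A first codon outside the mitochondrial start set is
    flagged, not fatal.
    """
    s = excise_inserts(gene_seq.upper(), frameshift_inserts)
    if len(s) < 6:
        raise ValueError(f"{gene or 'gene'}: too short to have start and stop")
    start = s[:3]
    trailing = len(s) % 3
    if trailing == 0:
        last = s[-3:]
        complete = last in STOP_CODONS
        stop = last
    else:
        tail = s[-trailing:]
        stop = {1: "T--", 2: "TA-"}[trailing] if tail in ("T", "TA") else tail + "-" * (3 - trailing)
        complete = False
    return CodonReport(gene=gene, species=species, start_codon=start,
                       stop_codon=stop, complete_stop=complete,
                       nonstandard_start=start not in START_CODONS,
                       internal_stop=has_internal_stop(s))


#: reporting class for both 1-nt and 2-nt truncated stops
INCOMPLETE_STOP_CLASS = "T-"


def _stop_class(report: CodonReport) -> str:
    if report.stop_codon in ("T--", "TA-"):
        return INCOMPLETE_STOP_CLASS
    return report.stop_codon


def usage_matrix(reports: list[CodonReport]):
    """Gene x codon count tables for starts and stops across a cohort.

    Returns ``(start_counts, stop_counts)`` as DataFrames with genes as rows.
    Reports carrying an internal stop are excluded from the tallies with a
    warning (a misframed annotation would otherwise pollute the cohort
    counts); truncated stops are pooled into the single class "T-".
    """
    import logging

    import pandas as pd

    if not reports:
        raise ValueError("no codon reports")
    usable = []
    for r in reports:
        if r.internal_stop:
            logging.getLogger("mitocomp").warning(
                "%s/%s: internal stop codon; excluded from usage matrix",
                r.species, r.gene)
            continue
        usable.append(r)
    genes = list(dict.fromkeys(r.gene for r in usable))
    start = pd.DataFrame(0, index=genes,
                         columns=sorted({r.start_codon for r in usable}))
    stop = pd.DataFrame(0, index=genes,
                        columns=sorted({_stop_class(r) for r in usable}))
    for r in usable:
        start.loc[r.gene, r.start_codon] += 1
        stop.loc[r.gene, _stop_class(r)] += 1
    return start, stop


def atg_start_fraction(start_counts) -> float:
    """Percentage of ATG among all start codons in a usage matrix."""
    total = start_counts.to_numpy().sum()
    atg = start_counts["ATG"].sum() if "ATG" in start_counts.columns else 0
    return 100.0 * atg / total if total else float("nan")


def strip_stops(aln: Alignment) -> Alignment:
    """Remove the terminal stop-codon column from a codon alignment.

    The alignment length must be a codon multiple.  An internal stop in any
    sequence is an error naming that sequence; if any sequence's final codon
    is a stop, the last codon column is dropped for all rows.
    """
    if aln.length % 3:
        raise ValueError("codon alignment length not divisible by 3")
    for label, row in zip(aln.labels, aln.rows):
        for i in range(0, aln.length - 3, 3):
            codon = row[i:i + 3]
            if codon in STOP_CODONS:
                raise ValueError(f"internal stop codon in {label} at column {i + 1}")
    if any(row[-3:] in STOP_CODONS for row in aln.rows):
        return Alignment(labels=list(aln.labels),
                         rows=[row[:-3] for row in aln.rows])
    return aln
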