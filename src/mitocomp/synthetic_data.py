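"""Synthetic mitogenome cohorts and codon-level evolution with known truth.

Every analysis stage in this package has a generative twin here, so the whole
pipeline can be exercised — and its estimates checked against planted truth —
without any downloaded data.  The generator emulates the statistical
structure the analyses assume:

* the conserved vertebrate/avian gene order (37 genes + control region, with
  ND6 and eight tRNAs on the light strand),
* per-region base composition with configurable AT/GC skews, realized by
  exact-count sampling (a shuffled multiset matching the target percentages,
  so regions of a few hundred bp sit within fractions of a point of target),
* planted gene overlaps (shared sequence, downstream feature taking
  precedence) and intergenic spacers,
* planted start/stop codons per protein-coding gene, including the
  incomplete stops T--/TA- and the ND3 single-C insertion,
* planted control-region tandem repeats,
* designed tRNA cloverleafs (and D-armless variants) with perfect stems, and
* codon sequence evolution along a tree under a transition/transversion bias
  kappa and a per-gene nonsynonymous acceptance ratio omega, simulated
  site-by-site with an exact Gillespie scheme that rejects stop codons.

What it deliberately does not model: indel evolution, genome rearrangement,
and among-site rate heterogeneity.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np

from .alignment_variation import Alignment, write_alignment
from .codon_usage import STOP_CODONS, excise_inserts
from .genome_model import (GeneFeature, GenomeAnnotation, MitoGenome,
                           revcomp, write_fasta, write_feature_table)
from .trna_fold import ANTICODONS

# (name, kind, strand) in the conserved avian mitochondrial order
GENE_ORDER: tuple[tuple[str, str, str], ...] = (
    ("tRNA-Phe", "tRNA", "H"), ("12S", "rRNA", "H"), ("tRNA-Val", "tRNA", "H"),
    ("16S", "rRNA", "H"), ("tRNA-Leu(UUR)", "tRNA", "H"), ("ND1", "PCG", "H"),
    ("tRNA-Ile", "tRNA", "H"), ("tRNA-Gln", "tRNA", "L"), ("tRNA-Met", "tRNA", "H"),
    ("ND2", "PCG", "H"), ("tRNA-Trp", "tRNA", "H"), ("tRNA-Ala", "tRNA", "L"),
    ("tRNA-Asn", "tRNA", "L"), ("tRNA-Cys", "tRNA", "L"), ("tRNA-Tyr", "tRNA", "L"),
    ("COI", "PCG", "H"), ("tRNA-Ser(UCN)", "tRNA", "L"), ("tRNA-Asp", "tRNA", "H"),
    ("COII", "PCG", "H"), ("tRNA-Lys", "tRNA", "H"), ("ATP8", "PCG", "H"),
    ("ATP6", "PCG", "H"), ("COIII", "PCG", "H"), ("tRNA-Gly", "tRNA", "H"),
    ("ND3", "PCG", "H"), ("tRNA-Arg", "tRNA", "H"), ("ND4L", "PCG", "H"),
    ("ND4", "PCG", "H"), ("tRNA-His", "tRNA", "H"), ("tRNA-Ser(AGY)", "tRNA", "H"),
    ("tRNA-Leu(CUN)", "tRNA", "H"), ("ND5", "PCG", "H"), ("CYTB", "PCG", "H"),
    ("tRNA-Thr", "tRNA", "H"), ("tRNA-Pro", "tRNA", "L"), ("ND6", "PCG", "L"),
    ("tRNA-Glu", "tRNA", "L"), ("CR", "CR", "H"),
)

#: default coding lengths (bp, incl. start and stop/stop-tail) per PCG —
#: typical shorebird values; COIII and ND4 end on the 1-nt incomplete stop
DEFAULT_PCG_LENGTHS = {
    "ND1": 978, "ND2": 1041, "COI": 1551, "COII": 684, "ATP8": 168,
    "ATP6": 684, "COIII": 784, "ND3": 351, "ND4L": 297, "ND4": 1378,
    "ND5": 1818, "CYTB": 1143, "ND6": 522,
}

DEFAULT_START_CODONS = {g: "ATG" for g in DEFAULT_PCG_LENGTHS} | {
    "COI": "GTG", "ND5": "GTG", "ND3": "ATT", "ND1": "ATA"}
DEFAULT_STOP_CODONS = {
    "ND1": "AGA", "ND2": "TAG", "COI": "AGG", "COII": "TAA", "ATP8": "TAA",
    "ATP6": "TAA", "COIII": "T--", "ND3": "TAA", "ND4L": "TAA", "ND4": "T--",
    "ND5": "AGA", "CYTB": "TAA", "ND6": "TAG"}

#: per-gene omega defaults mirroring the purifying-selection gradient seen
#: in shorebird mitogenomes (ATP8 weakly, COI strongly constrained)
DEFAULT_GENE_OMEGA = {
    "ND1": 0.05, "ND2": 0.08, "COI": 0.01, "COII": 0.03, "ATP8": 0.16,
    "ATP6": 0.07, "COIII": 0.03, "ND3": 0.06, "ND4L": 0.06, "ND4": 0.06,
    "ND5": 0.07, "CYTB": 0.04, "ND6": 0.09,
}


@dataclass
class SimConfig:
    """Genome-level simulation settings; the defaults are the study-style
    conditions every planted-truth test runs under."""

    genome_id: str = "synthetic"
    # composition targets as (pct A, pct C, pct G, pct T); "default" applies
    # to every region without its own entry.  The default whole-genome target
    # has the positive AT skew / negative GC skew typical of the heavy strand.
    composition: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {"default": (31.0, 30.0, 14.0, 25.0),
                                 "CR": (32.0, 28.0, 11.5, 28.5)})
    pcg_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PCG_LENGTHS))
    start_codons: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_START_CODONS))
    stop_codons: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STOP_CODONS))
    rrna_lengths: dict[str, int] = field(
        default_factory=lambda: {"12S": 975, "16S": 1600})
    # (upstream, downstream, overlap bp): shared sequence, downstream wins
    overlaps: tuple[tuple[str, str, int], ...] = (
        ("ATP8", "ATP6", 10), ("ATP6", "COIII", 1))
    # (upstream, downstream, spacer bp)
    spacers: tuple[tuple[str, str, int], ...] = (
        ("tRNA-Gly", "ND3", 1), ("ND3", "tRNA-Arg", 2),
        ("CYTB", "tRNA-Thr", 2), ("tRNA-Thr", "tRNA-Pro", 3))
    # control-region repeat plan: (motif, copies)
    cr_repeats: tuple[tuple[str, int], ...] = (("AAACAAC", 8), ("AAAC", 6))
    cr_unique_range: tuple[int, int] = (150, 450)
    # ND3 single-C insertion at gene-relative 1-based position 174
    nd3_extra_c: bool = True
    d_armless_trnas: tuple[str, ...] = ("tRNA-Ser(AGY)",)
    seed: int = 0


@dataclass
class GeneEvolParams:
    """Codon-evolution settings for one gene along one tree."""

    tree: str                 # newick with branch lengths and leaf labels
    omega: float = 0.2        # nonsynonymous acceptance ratio
    kappa: float = 2.0        # transition/transversion rate ratio
    n_codons: int = 500
    seed: int = 0
    root_seq: str | None = None      # coding-sense, length multiple of 3
    frozen_codons: tuple[int, ...] = ()


@dataclass
class TruthRecord:
    """Planted values, serialized losslessly as flat key<TAB>value text."""

    values: dict[str, object] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for k in sorted(self.values):
                fh.write(f"{k}\t{self.values[k]}\n")

    @classmethod
    def read(cls, path) -> "TruthRecord":
        values: dict[str, object] = {}
        with open(path) as fh:
            for line in fh:
                k, _, v = line.rstrip("\n").partition("\t")
                values[k] = v
        return cls(values=values)


# ---------------------------------------------------------------------------
# Composition-controlled sequence pieces
# ---------------------------------------------------------------------------

def _exact_count_seq(rng: np.random.Generator, length: int,
                     comp: tuple[float, float, float, float]) -> str:
    """Shuffled base multiset whose counts match the target percentages to
    within rounding — composition control without a dinucleotide model."""
    pa, pc, pg, pt = comp
    if abs(pa + pc + pg + pt - 100.0) > 1e-6:
        raise ValueError("composition targets must sum to 100")
    raw = [pa * length / 100, pc * length / 100, pg * length / 100, pt * length / 100]
    counts = [int(math.floor(x)) for x in raw]
    rema = sorted(range(4), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(length - sum(counts)):
        counts[rema[i % 4]] += 1
    arr = np.array(list("A" * counts[0] + "C" * counts[1] + "G" * counts[2]
                        + "T" * counts[3]))
    rng.shuffle(arr)
    return "".join(arr)


def _pcg_coding(rng: np.random.Generator, gene: str, length: int, start: str,
                stop_spec: str, comp, forced: dict[int, str] | None = None) -> str:
    """Coding-sense PCG sequence with planted start/stop and no internal stop.

    ``stop_spec`` is a complete stop codon or the truncated classes "TA-" /
    "T--"; ``forced`` pins individual positions (used to make planted
    overlaps consistent with the upstream gene's stop).  In-frame internal
    stops are repaired by *swapping* a base of the stop codon with a
    same-sequence position holding a different base, so the exact-count
    composition control survives the repair.
    """
    tail = stop_spec.replace("-", "")
    if len(tail) == 3 and stop_spec not in STOP_CODONS:
        raise ValueError(f"{gene}: {stop_spec!r} is not a stop codon")
    expected_mod = len(tail) % 3
    if length % 3 != expected_mod:
        raise ValueError(f"{gene}: length {length} inconsistent with stop {stop_spec!r}")
    body_len = length - 3 - len(tail)
    if body_len < 0:
        raise ValueError(f"{gene}: length {length} too short")
    seq = list(start + _exact_count_seq(rng, body_len, comp) + tail)
    forced = forced or {}
    for pos, base in forced.items():
        if pos < 3 and seq[pos] != base:
            raise ValueError(f"{gene}: forced base at {pos} conflicts with start codon")
        seq[pos] = base
    n_complete = length // 3
    last_full = n_complete - 1 if expected_mod == 0 else n_complete

    def codon_at(pos: int) -> str:
        ci = pos // 3
        return "".join(seq[3 * ci:3 * ci + 3])

    body_positions = [p for p in range(3, 3 + body_len) if p not in forced]
    for ci in range(1, last_full):
        codon = "".join(seq[3 * ci:3 * ci + 3])
        if codon not in STOP_CODONS:
            continue
        repaired = False
        for _ in range(500):
            off = int(rng.integers(3))
            pos = 3 * ci + off
            if pos in forced:
                continue
            q = int(body_positions[int(rng.integers(len(body_positions)))])
            if q // 3 == ci or seq[q] == seq[pos]:
                continue
            seq[pos], seq[q] = seq[q], seq[pos]
            if (codon_at(pos) not in STOP_CODONS
                    and (q // 3 >= last_full or q < 3
                         or codon_at(q) not in STOP_CODONS)):
                repaired = True
                break
            seq[pos], seq[q] = seq[q], seq[pos]  # undo and retry
        if not repaired:
            raise ValueError(f"{gene}: cannot repair stop at codon {ci}")
    return "".join(seq)


def design_trna(rng: np.random.Generator, name: str,
                d_armless: bool = False) -> tuple[str, dict]:
    """A tRNA gene with perfect Watson-Crick stems and all-A loops.

    Stems are drawn from {G, C} so that any shifted fold would run into the
    unpairable A loops; the anticodon sits at loop positions 3-5.  Returns
    the sequence and a truth dict (class, arm lengths, anticodon).
    """
    def stem(k):
        s5 = "".join(rng.choice(list("GC"), size=k))
        return s5, revcomp(s5)

    anticodon = ANTICODONS[name]
    acc5, acc3 = stem(7)
    ac5, ac3 = stem(5)
    t5, t3 = stem(5)
    t_loop = 7
    var = 4
    ac_loop = "AA" + anticodon + "AA"
    if d_armless:
        connector = int(rng.integers(4, 7))
        seq = (acc5 + "A" * connector + ac5 + ac_loop + ac3 + "A" * var
               + t5 + "A" * t_loop + t3 + acc3 + "A")
        truth = {"class": "D-armless", "d_loop": connector}
    else:
        d5, d3 = stem(4)
        d_loop = int(rng.integers(5, 11))
        seq = (acc5 + d5 + "A" * d_loop + d3 + ac5 + ac_loop + ac3
               + "A" * var + t5 + "A" * t_loop + t3 + acc3 + "A")
        truth = {"class": "cloverleaf", "d_loop": d_loop}
    truth.update({"anticodon": anticodon, "length": len(seq)})
    return seq, truth


def _cr_sequence(rng: np.random.Generator, cfg: SimConfig) -> tuple[str, dict]:
    """Control region: unique blocks alternating with planted tandem arrays.

    The unique blocks are drawn from a shared base pool whose counts are the
    CR composition target minus what the planted repeat arrays contribute,
    so the region as a whole hits its target despite the arrays being
    strongly A/C-biased.  The assembled region is verified to contain the
    planted arrays as its only detectable repeats (redrawn otherwise).
    """
    from .tandem_repeats import find_tandem_repeats

    for _ in range(50):
        try:
            seq, truth = _cr_sequence_attempt(rng, cfg)
        except RuntimeError:
            continue  # pathological block draw; redraw lengths and pool
        got = [(r.motif, r.copies) for r in find_tandem_repeats(seq)]
        want = [(m, float(c)) for m, c in cfg.cr_repeats]
        if got == want:
            return seq, truth
    raise RuntimeError("could not realize the planted repeat architecture")


def _cr_sequence_attempt(rng: np.random.Generator, cfg: SimConfig
                         ) -> tuple[str, dict]:
    from .tandem_repeats import find_tandem_repeats

    comp = cfg.composition.get("CR", cfg.composition["default"])
    lo, hi = cfg.cr_unique_range
    arrays = []
    for motif, copies in cfg.cr_repeats:
        if copies < 2:
            raise ValueError("planted repeats need at least 2 copies")
        arrays.append(motif * copies)
    n_blocks = len(arrays) + 1
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_blocks)]
    unique_total = sum(lengths)
    total = unique_total + sum(len(a) for a in arrays)

    rep_counts = {b: sum(a.count(b) for a in arrays) for b in "ACGT"}
    target = dict(zip("ACGT", (comp[0], comp[1], comp[2], comp[3])))
    raw = {b: max(target[b] * total / 100 - rep_counts[b], 0.0) for b in "ACGT"}
    scale = unique_total / sum(raw.values())
    needed = {b: int(math.floor(raw[b] * scale)) for b in "ACGT"}
    by_frac = sorted("ACGT", key=lambda b: raw[b] * scale - needed[b],
                     reverse=True)
    for i in range(unique_total - sum(needed.values())):
        needed[by_frac[i % 4]] += 1
    pool = list("".join(b * needed[b] for b in "ACGT"))
    rng.shuffle(pool)

    blocks = []
    offset = 0
    for L in lengths:
        chars = pool[offset:offset + L]
        offset += L
        for _ in range(80):  # reject shuffles containing a detectable run
            block = "".join(chars)
            if not find_tandem_repeats(block):
                break
            rng.shuffle(chars)
        else:
            raise RuntimeError("could not draw a repeat-free unique block")
        blocks.append(block)

    def fix_junction(block: str, pos: int, bad: str) -> str:
        # a flanking base equal to the motif's period-offset base would
        # extend the planted run by a fractional copy; swap it inward
        if block[pos] != bad:
            return block
        inner = [i for i in range(1, len(block) - 1) if block[i] != bad]
        if not inner:
            return block[:-1] + "G" if pos != 0 else "G" + block[1:]
        i = int(inner[int(rng.integers(len(inner)))])
        lst = list(block)
        lst[pos], lst[i] = lst[i], lst[pos]
        return "".join(lst)

    parts = [blocks[0]]
    truth: dict[str, object] = {}
    for i, ((motif, copies), array) in enumerate(zip(cfg.cr_repeats, arrays)):
        parts[-1] = fix_junction(parts[-1], -1, motif[-1])
        parts.append(array)
        truth[f"repeat.{i}.motif"] = motif
        truth[f"repeat.{i}.copies"] = copies
        parts.append(fix_junction(blocks[i + 1], 0, motif[0]))
    seq = "".join(parts)
    truth["cr_length"] = len(seq)
    return seq, truth


# ---------------------------------------------------------------------------
# Whole-genome assembly
# ---------------------------------------------------------------------------

def _overlap_constraints(cfg: SimConfig) -> dict[str, dict[int, str]]:
    """Forced bases on downstream overlap partners so the upstream gene's
    planted stop survives the downstream overwrite."""
    forced: dict[str, dict[int, str]] = {}
    for up, down, k in cfg.overlaps:
        if up not in cfg.pcg_lengths or down not in cfg.pcg_lengths:
            continue  # non-PCG overlaps need no codon protection
        if k > cfg.pcg_lengths[up]:
            raise ValueError(f"overlap {up}/{down} longer than {up}")
        stop = cfg.stop_codons[up].replace("-", "")
        want = forced.setdefault(down, {})
        for i, base in enumerate(stop):
            pos = k - len(stop) + i
            if pos >= 0:
                want[pos] = base
    return forced


def _pcg_overlaps(cfg: SimConfig) -> list[tuple[str, str, int]]:
    return [(up, down, k) for up, down, k in cfg.overlaps
            if up in cfg.pcg_lengths and down in cfg.pcg_lengths]


def _junction_frame_safe(down_head: str, up_len: int, k: int) -> bool:
    """No stop codon in the upstream gene's frame among the codons that fall
    entirely inside the shared overlap (the final, pinned stop excepted)."""
    for j in range(k - 2):
        if (up_len - k + j) % 3 == 0 and j != k - 3:
            if down_head[j:j + 3] in STOP_CODONS:
                return False
    return True


def _region_sequences(rng: np.random.Generator, cfg: SimConfig
                      ) -> tuple[dict[str, str], TruthRecord]:
    """Coding-sense sequence for every region, plus the planted truth.

    Genes that overlap a downstream protein-coding gene are generated after
    it: their shared tail is forced to equal the downstream head (downstream
    precedence), the head having been drawn so that it spells no stop codon
    in the upstream frame.  This keeps every planted start/stop codon and
    every reading frame intact through the overlap overwrites at assembly.
    """
    truth = TruthRecord()
    forced_map = _overlap_constraints(cfg)
    overlaps = _pcg_overlaps(cfg)
    up_of = {up: (down, k) for up, down, k in overlaps}
    down_of = {down: (up, k) for up, down, k in overlaps}

    def gen_pcg(name: str) -> str:
        comp = cfg.composition.get(name, cfg.composition["default"])
        forced = dict(forced_map.get(name, {}))
        if name in up_of:
            down, k = up_of[name]
            L = cfg.pcg_lengths[name]
            forced.update({L - k + i: b for i, b in enumerate(seqs[down][:k])})
        for _ in range(100):
            s = _pcg_coding(rng, name, cfg.pcg_lengths[name],
                            cfg.start_codons[name], cfg.stop_codons[name],
                            comp, forced)
            if name not in down_of:
                break
            up, k = down_of[name]
            if _junction_frame_safe(s[:k], cfg.pcg_lengths[up], k):
                break
        else:
            raise ValueError(f"{name}: cannot satisfy overlap frame constraints")
        return s

    seqs: dict[str, str] = {}
    deferred: list[str] = []
    for name, kind, strand in GENE_ORDER:
        comp = cfg.composition.get(name, cfg.composition["default"])
        if kind == "PCG":
            if name in up_of:
                deferred.append(name)  # needs the downstream head first
                continue
            seqs[name] = gen_pcg(name)
        elif kind == "rRNA":
            seqs[name] = _exact_count_seq(rng, cfg.rrna_lengths[name], comp)
        elif kind == "tRNA":
            s, ttruth = design_trna(rng, name, name in cfg.d_armless_trnas)
            for k, v in ttruth.items():
                truth.values[f"trna.{name}.{k}"] = v
            seqs[name] = s
        else:  # CR
            s, ctruth = _cr_sequence(rng, cfg)
            truth.values.update(ctruth)
            seqs[name] = s
    while deferred:
        ready = [n for n in deferred if up_of[n][0] in seqs]
        if not ready:
            raise ValueError(f"unresolvable overlap chain among {deferred}")
        for name in ready:
            seqs[name] = gen_pcg(name)
            deferred.remove(name)

    for name, kind, _ in GENE_ORDER:
        if kind != "PCG":
            continue
        if name == "ND3" and cfg.nd3_extra_c:
            seqs[name] = seqs[name][:173] + "C" + seqs[name][173:]
            truth.values["codon.ND3.insert"] = 174
        truth.values[f"codon.{name}.start"] = cfg.start_codons[name]
        truth.values[f"codon.{name}.stop"] = cfg.stop_codons[name]
    return seqs, truth


def _assemble(seqs: dict[str, str], cfg: SimConfig
              ) -> tuple[MitoGenome, GenomeAnnotation]:
    """Place region sequences in gene order, honoring planted spacers and
    overlaps (downstream sequence wins in shared stretches)."""
    overlap_at = {down: k for _, down, k in cfg.overlaps}
    overlap_up = {down: up for up, down, _ in cfg.overlaps}
    spacer_at = {down: g for _, down, g in cfg.spacers}
    buf: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    prev_name = None
    for name, kind, strand in GENE_ORDER:
        placed = revcomp(seqs[name]) if strand == "L" else seqs[name]
        start = pos
        if name in overlap_at and overlap_up.get(name) == prev_name:
            start -= overlap_at[name]
        elif name in spacer_at:
            gap = spacer_at[name]
            comp = cfg.composition["default"]
            spacer_seed = (cfg.seed * 1000003 + zlib.crc32(name.encode())) % 2**31
            filler = "".join(
                np.random.default_rng(spacer_seed)
                .choice(list("ACGT"), size=gap,
                        p=[c / 100 for c in comp]))
            buf.extend(filler)
            start += gap
        end = start + len(placed)
        for i, ch in enumerate(placed):
            idx = start + i
            if idx < len(buf):
                buf[idx] = ch
            else:
                buf.append(ch)
        inserts = (174,) if (name == "ND3" and cfg.nd3_extra_c) else ()
        features.append(GeneFeature(name=name, kind=kind, start=start, end=end,
                                    strand=strand, frameshift_inserts=inserts))
        pos = end
        prev_name = name
    genome = MitoGenome(id=cfg.genome_id, sequence="".join(buf))
    return genome, GenomeAnnotation(features=features, genome_id=cfg.genome_id)


def generate_mitogenome(cfg: SimConfig | None = None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[MitoGenome, GenomeAnnotation, TruthRecord]:
    """Deterministically generate one annotated synthetic mitogenome."""
    cfg = cfg or SimConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    seqs, truth = _region_sequences(rng, cfg)
    genome, annotation = _assemble(seqs, cfg)
    truth.values["size"] = genome.length
    for name, comp in cfg.composition.items():
        pa, pc, pg, pt = comp
        truth.values[f"comp.{name}.at_skew_sign"] = int(np.sign(pa - pt))
        truth.values[f"comp.{name}.gc_skew_sign"] = int(np.sign(pg - pc))
    return genome, annotation, truth


# ---------------------------------------------------------------------------
# Codon evolution
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _codon_list():
    return [a + b + c for a in _BASES for b in _BASES for c in _BASES]


def _rate_tables(omega: float, kappa: float):
    """Per-codon substitution targets and rates for the thinned process.

    Transition rates carry weight 3*kappa/(kappa+2) and transversions
    3/(kappa+2) (mean nucleotide rate 1); nonsynonymous changes are further
    multiplied by omega; changes into stops have rate zero.  With these
    units a branch of length b yields about b substitutions per codon site
    when omega = 1.
    """
    from .codon_usage import MITO_CODE
    k_ts = 3.0 * kappa / (kappa + 2.0)
    k_tv = 3.0 / (kappa + 2.0)
    codons = _codon_list()
    targets: list[np.ndarray] = []
    rates: list[np.ndarray] = []
    totals = np.zeros(64)
    for ci, codon in enumerate(codons):
        tg, rt = [], []
        if codon not in STOP_CODONS:
            aa = MITO_CODE[codon]
            for pos in range(3):
                for b in _BASES:
                    if b == codon[pos]:
                        continue
                    mut = codon[:pos] + b + codon[pos + 1:]
                    if mut in STOP_CODONS:
                        continue
                    r = (k_ts if (codon[pos], b) in _TRANSITION else k_tv) / 3.0
                    if MITO_CODE[mut] != aa:
                        r *= omega
                    if r > 0:
                        tg.append(codons.index(mut))
                        rt.append(r)
        targets.append(np.array(tg, dtype=np.int64))
        rates.append(np.array(rt))
        totals[ci] = sum(rt)
    return targets, rates, totals


def _evolve_branch(seq: np.ndarray, bl: float, tables, rng: np.random.Generator,
                   frozen: frozenset[int]) -> np.ndarray:
    targets, rates, totals = tables
    out = seq.copy()
    tau = bl / 3.0
    for site in range(out.size):
        if site in frozen:
            continue
        c = int(out[site])
        t = 0.0
        while True:
            total = totals[c]
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= tau:
                break
            u = rng.random() * total
            cum = np.cumsum(rates[c])
            c = int(targets[c][int(np.searchsorted(cum, u))])
        out[site] = c
    return out


def _encode(seq: str) -> np.ndarray:
    codons = _codon_list()
    idx = {c: i for i, c in enumerate(codons)}
    return np.array([idx[seq[3 * i:3 * i + 3]] for i in range(len(seq) // 3)],
                    dtype=np.int64)


def _decode(arr: np.ndarray) -> str:
    codons = _codon_list()
    return "".join(codons[int(i)] for i in arr)


def evolve_gene_alignment(params: GeneEvolParams
                          ) -> tuple[Alignment, TruthRecord]:
    """Evolve one codon alignment along a tree; deterministic given seed.

    The root sequence is drawn uniformly over sense codons unless supplied;
    substitutions are simulated per site with an exact Gillespie scheme under
    the kappa/omega-thinned rates, never passing through a stop codon.
    """
    if params.n_codons <= 0:
        raise ValueError("n_codons must be positive")
    rng = np.random.default_rng(params.seed)
    tables = _rate_tables(params.omega, params.kappa)
    tree = dendropy.Tree.get(data=params.tree, schema="newick")
    frozen = frozenset(params.frozen_codons)

    if params.root_seq is not None:
        root = _encode(params.root_seq.upper())
        if root.size != params.n_codons:
            raise ValueError("root_seq length disagrees with n_codons")
    else:
        sense = np.array([i for i, c in enumerate(_codon_list())
                          if c not in STOP_CODONS])
        root = rng.choice(sense, size=params.n_codons)

    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root}
    labels, rows = [], []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            cur = root
        else:
            bl = node.edge.length or 0.0
            cur = _evolve_branch(seqs[id(node.parent_node)], bl, tables, rng,
                                 frozen)
            seqs[id(node)] = cur
        if node.is_leaf():
            labels.append(node.taxon.label if node.taxon else f"leaf{len(labels)}")
            rows.append(_decode(cur))
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    aln = Alignment(labels=[labels[i] for i in order],
                    rows=[rows[i] for i in order])
    truth = TruthRecord(values={"omega": params.omega, "kappa": params.kappa,
                                "n_codons": params.n_codons,
                                "tree": params.tree.strip()})
    return aln, truth


def random_tree(labels: list[str], rng: np.random.Generator,
                bl_range: tuple[float, float] = (0.02, 0.08)) -> str:
    """Random binary topology by sequential joining, uniform branch lengths."""
    lo, hi = bl_range

    def bl() -> str:
        return f"{rng.uniform(lo, hi):.6f}"

    nodes = [f"{lbl}:{bl()}" for lbl in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{bl()}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(n: int, cfg: SimConfig | None = None, out_dir=None,
                    seed: int | None = None,
                    bl_range: tuple[float, float] = (0.02, 0.08),
                    gene_omega: dict[str, float] | None = None):
    """Generate ``n`` genomes with per-gene alignable orthologs.

    A root genome is generated from ``cfg``; each PCG is then evolved along a
    shared random tree under its own omega (first and last codons, and any
    overlap-constrained codons, are held fixed so planted codons and overlaps
    stay intact cohort-wide).  tRNAs are redesigned per taxon (D-loop lengths
    vary, planted classes do not), rRNAs accumulate light point substitution,
    and the control region is regenerated per taxon with the planted repeat
    plan but varying unique-block lengths.  Returns
    ``(genomes, alignments, truth)`` where genomes is a list of
    (MitoGenome, GenomeAnnotation) and alignments maps gene -> Alignment;
    with ``out_dir`` everything is also written as FASTA + feature tables +
    per-gene alignment FASTA + a truth file.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    cfg = cfg or SimConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    gene_omega = gene_omega or dict(DEFAULT_GENE_OMEGA)

    root_cfg = replace(cfg, genome_id=f"{cfg.genome_id}_root")
    root_seqs, root_truth = _region_sequences(rng, root_cfg)
    taxa = [f"taxon{str(i + 1).zfill(2)}" for i in range(n)]
    tree = random_tree(taxa, rng, bl_range)

    overlaps = _pcg_overlaps(cfg)
    alignments: dict[str, Alignment] = {}
    per_taxon_pcg: dict[str, dict[str, str]] = {t: {} for t in taxa}
    for gene in [g for g, k, _ in GENE_ORDER if k == "PCG"]:
        coding = root_seqs[gene]
        if gene == "ND3" and cfg.nd3_extra_c:
            coding = excise_inserts(coding, (174,))
        n_full = len(coding) // 3
        tail = coding[3 * n_full:]
        # start, stop and every codon touching a planted overlap junction
        # stay fixed, so the shared sequence is identical across the cohort
        frozen = {0, n_full - 1}
        for up, down, k in overlaps:
            if gene == down:
                frozen.update(range(0, (k - 1) // 3 + 1))
            if gene == up:
                frozen.update(range((len(coding) - k) // 3, n_full))
        aln, _ = evolve_gene_alignment(GeneEvolParams(
            tree=tree, omega=gene_omega.get(gene, 0.05),
            n_codons=n_full, seed=int(rng.integers(2**31)),
            root_seq=coding[:3 * n_full], frozen_codons=tuple(sorted(frozen))))
        alignments[gene] = aln
        for label, row in zip(aln.labels, aln.rows):
            s = row + tail
            if gene == "ND3" and cfg.nd3_extra_c:
                s = s[:173] + "C" + s[173:]
            per_taxon_pcg[label][gene] = s

    genomes = []
    truth = TruthRecord(values={"tree": tree, "n": n})
    truth.values.update({f"root.{k}": v for k, v in root_truth.values.items()})
    for gene, om in gene_omega.items():
        truth.values[f"omega.{gene}"] = om
    for t in taxa:
        taxon_rng = np.random.default_rng(int(rng.integers(2**31)))
        seqs = dict(root_seqs)
        seqs.update(per_taxon_pcg[t])
        for name, kind, _ in GENE_ORDER:
            if kind == "tRNA":
                s, ttruth = design_trna(taxon_rng, name,
                                        name in cfg.d_armless_trnas)
                seqs[name] = s
                truth.values[f"{t}.trna.{name}.class"] = ttruth["class"]
                truth.values[f"{t}.trna.{name}.d_loop"] = ttruth["d_loop"]
            elif kind == "rRNA":
                base = np.array(list(root_seqs[name]))
                mask = taxon_rng.random(base.size) < 0.03
                if mask.any():
                    base[mask] = taxon_rng.choice(list("ACGT"), size=int(mask.sum()))
                seqs[name] = "".join(base)
            elif kind == "CR":
                s, ctruth = _cr_sequence(taxon_rng, cfg)
                seqs[name] = s
                for k, v in ctruth.items():
                    truth.values[f"{t}.{k}"] = v
        genome, annotation = _assemble(seqs, replace(cfg, genome_id=t))
        truth.values[f"{t}.size"] = genome.length
        genomes.append((genome, annotation))

    if out_dir is not None:
        out = Path(out_dir)
        (out / "alignments").mkdir(parents=True, exist_ok=True)
        for genome, annotation in genomes:
            write_fasta(genome, out / f"{genome.id}.fasta")
            write_feature_table(annotation, out / f"{genome.id}.features.tsv")
        for gene, aln in alignments.items():
            write_alignment(aln, out / "alignments" / f"{gene}.fasta")
        truth.write(out / "truth.tsv")
    return genomes, alignments, truth
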