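"""Constrained cloverleaf folding for mitochondrial tRNA genes.

Mitochondrial tRNAs (55-95 nt) fold into the canonical cloverleaf: a 7-bp
acceptor stem, a D (dihydrouridine) arm, a 5-bp anticodon stem with a 7-nt
loop carrying the anticodon at loop positions 3-5, a short variable region,
and a T(psi)C arm, followed by an unpaired discriminator base at the 3' end
(the CCA tail is added post-transcriptionally and is not genome-encoded).
Animal mitochondria also tolerate truncated tRNAs: tRNA-Ser(AGY) typically
lacks the D arm altogether, its place taken by a short connector loop.

Rather than thermodynamic (nearest-neighbour energy) folding, this module
scores candidate cloverleafs with integer pair scores (G.C = 3, A.T = 2,
G.U = 1, at most one unscored mismatch per stem) and exhaustively searches
every admissible partition of the sequence into arms within the allowed
length ranges.  The integer scoring makes the optimum exactly reproducible
and checkable by brute-force enumeration.  The D-armless model competes with
the canonical one only when allowed, and wins only on a strictly higher
score; remaining ties prefer the smaller D-loop, then the smaller variable
region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codon_usage import MITO_CODE
from .genome_model import revcomp

#: canonical anticodons (DNA alphabet) of the 22 vertebrate mito tRNAs
ANTICODONS = {
    "tRNA-Phe": "GAA", "tRNA-Val": "TAC", "tRNA-Leu(UUR)": "TAA",
    "tRNA-Leu(CUN)": "TAG", "tRNA-Ile": "GAT", "tRNA-Gln": "TTG",
    "tRNA-Met": "CAT", "tRNA-Trp": "TCA", "tRNA-Ala": "TGC",
    "tRNA-Asn": "GTT", "tRNA-Cys": "GCA", "tRNA-Tyr": "GTA",
    "tRNA-Ser(UCN)": "TGA", "tRNA-Asp": "GTC", "tRNA-Lys": "TTT",
    "tRNA-Gly": "TCC", "tRNA-Arg": "TCG", "tRNA-His": "GTG",
    "tRNA-Ser(AGY)": "GCT", "tRNA-Glu": "TTC", "tRNA-Thr": "TGT",
    "tRNA-Pro": "TGG",
}

_AA3_TO_1 = {
    "Phe": "F", "Val": "V", "Leu": "L", "Ile": "I", "Gln": "Q", "Met": "M",
    "Trp": "W", "Ala": "A", "Asn": "N", "Cys": "C", "Tyr": "Y", "Ser": "S",
    "Asp": "D", "Lys": "K", "Gly": "G", "Arg": "R", "His": "H", "Glu": "E",
    "Thr": "T", "Pro": "P",
}

PAIR_SCORES = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2,
               ("G", "T"): 1, ("T", "G"): 1}


@dataclass
class FoldParams:
    acceptor_stem: int = 7
    d_stem: tuple[int, int] = (3, 4)
    d_loop: tuple[int, int] = (4, 12)
    ac_stem: int = 5
    ac_loop: int = 7
    variable: tuple[int, int] = (3, 23)
    t_stem: tuple[int, int] = (4, 5)
    t_loop: tuple[int, int] = (5, 9)
    max_mismatch_per_stem: int = 1


@dataclass
class CloverleafStructure:
    """One folded tRNA; ``model`` is cloverleaf / D-armless / unfoldable."""

    model: str
    score: int
    sequence: str
    pairs: list[tuple[int, int]] = field(default_factory=list)
    arms: dict[str, tuple[int, int]] = field(default_factory=dict)
    anticodon: str = ""

    @property
    def foldable(self) -> bool:
        return self.model != "unfoldable"

    @property
    def dot_bracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)

    def arm_length(self, arm: str) -> int:
        if arm not in self.arms:
            return 0
        a, b = self.arms[arm]
        return b - a

    def describe(self) -> str:
        """Dot-bracket plus annotated arm intervals (1-based)."""
        lines = [self.sequence, self.dot_bracket,
                 f"model={self.model} score={self.score} anticodon={self.anticodon}"]
        for arm, (a, b) in sorted(self.arms.items(), key=lambda kv: kv[1]):
            lines.append(f"  {arm}: {a + 1}..{b}")
        return "\n".join(lines)


def _stem_score(seq: str, s5: tuple[int, int], s3: tuple[int, int],
                max_mismatch: int):
    """Score a stem pairing seq[s5] against the reverse of seq[s3].

    Returns (score, pairs) or None when the mismatch budget is exceeded.
    Mismatched positions stay unpaired and score 0.
    """
    a0, a1 = s5
    b0, b1 = s3
    score = 0
    mismatches = 0
    pairs = []
    for k in range(a1 - a0):
        i, j = a0 + k, b1 - 1 - k
        val = PAIR_SCORES.get((seq[i], seq[j]))
        if val is None:
            mismatches += 1
            if mismatches > max_mismatch:
                return None
        else:
            score += val
            pairs.append((i, j))
    return score, pairs


def _evaluate(seq: str, params: FoldParams, ds: int, dl: int, v: int,
              ts: int, tl: int, d_armless: bool):
    """Score one arm-boundary partition; None when a stem fails."""
    n = len(seq)
    mm = params.max_mismatch_per_stem
    pos = params.acceptor_stem
    arms = {"acceptor5": (0, params.acceptor_stem)}
    total = 0
    pairs: list[tuple[int, int]] = []

    res = _stem_score(seq, (0, params.acceptor_stem), (n - 1 - params.acceptor_stem, n - 1), mm)
    if res is None:
        return None
    total += res[0]
    pairs += res[1]

    if d_armless:
        arms["d_replacement_loop"] = (pos, pos + dl)
        pos += dl
    else:
        d5 = (pos, pos + ds)
        dloop = (pos + ds, pos + ds + dl)
        d3 = (pos + ds + dl, pos + 2 * ds + dl)
        res = _stem_score(seq, d5, d3, mm)
        if res is None:
            return None
        total += res[0]
        pairs += res[1]
        arms["d_stem5"], arms["d_loop"], arms["d_stem3"] = d5, dloop, d3
        pos += 2 * ds + dl

    ac5 = (pos, pos + params.ac_stem)
    acloop = (pos + params.ac_stem, pos + params.ac_stem + params.ac_loop)
    ac3 = (acloop[1], acloop[1] + params.ac_stem)
    res = _stem_score(seq, ac5, ac3, mm)
    if res is None:
        return None
    total += res[0]
    pairs += res[1]
    arms["ac_stem5"], arms["ac_loop"], arms["ac_stem3"] = ac5, acloop, ac3
    pos = ac3[1]

    arms["variable"] = (pos, pos + v)
    pos += v

    t5 = (pos, pos + ts)
    tloop = (pos + ts, pos + ts + tl)
    t3 = (tloop[1], tloop[1] + ts)
    res = _stem_score(seq, t5, t3, mm)
    if res is None:
        return None
    total += res[0]
    pairs += res[1]
    arms["t_stem5"], arms["t_loop"], arms["t_stem3"] = t5, tloop, t3
    pos = t3[1]

    arms["acceptor3"] = (pos, pos + params.acceptor_stem)
    arms["discriminator"] = (n - 1, n)
    anticodon = seq[acloop[0] + 2:acloop[0] + 5]
    return total, pairs, arms, anticodon


def fold_trna(seq: str, params: FoldParams | None = None,
              allow_no_D: bool = False) -> CloverleafStructure:
    """Best-scoring cloverleaf over all admissible arm partitions.

    The search enumerates every combination of D-stem, D-loop, variable and
    T-arm lengths whose total matches the sequence; the variable-region
    length is implied by the others.  With ``allow_no_D`` the D-armless
    model competes, winning only on a strictly higher score.  Returns an
    explicit unfoldable result when no partition satisfies the stem
    constraints.
    """
    params = params or FoldParams()
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    if not 55 <= n <= 95:
        raise ValueError(f"tRNA length {n} outside 55-95 nt")
    core = n - 2 * params.acceptor_stem - 1
    fixed_ac = 2 * params.ac_stem + params.ac_loop

    best = None  # (score, model_rank, d_loop, variable, result, model_name)
    for ts in range(params.t_stem[0], params.t_stem[1] + 1):
        for tl in range(params.t_loop[0], params.t_loop[1] + 1):
            for dl in range(params.d_loop[0], params.d_loop[1] + 1):
                for ds in range(params.d_stem[0], params.d_stem[1] + 1):
                    v = core - (2 * ds + dl) - fixed_ac - (2 * ts + tl)
                    if not params.variable[0] <= v <= params.variable[1]:
                        continue
                    res = _evaluate(seq, params, ds, dl, v, ts, tl, False)
                    if res is None:
                        continue
                    key = (-res[0], 0, dl, v, ts, tl)
                    if best is None or key < best[0]:
                        best = (key, res, "cloverleaf")
                if not allow_no_D:
                    continue
                v = core - dl - fixed_ac - (2 * ts + tl)
                if not params.variable[0] <= v <= params.variable[1]:
                    continue
                res = _evaluate(seq, params, 0, dl, v, ts, tl, True)
                if res is None:
                    continue
                # D-armless wins only on strictly higher score: the rank-1
                # entry sorts after every cloverleaf of equal score.
                key = (-res[0], 1, dl, v, ts, tl)
                if best is None or key < best[0]:
                    best = (key, res, "D-armless")

    if best is None:
        return CloverleafStructure(model="unfoldable", score=0, sequence=seq)
    (_, res, model) = best
    score, pairs, arms, anticodon = res
    return CloverleafStructure(model=model, score=score, sequence=seq,
                               pairs=sorted(pairs), arms=arms,
                               anticodon=anticodon)


def anticodon_check(structure: CloverleafStructure, gene_name: str) -> bool:
    """Does the folded anticodon decode to the amino acid the tRNA is named
    for?  Isoacceptor classes — Ser(AGY)/Ser(UCN) and Leu(UUR)/Leu(CUN) —
    are distinguished by the codon family the anticodon reads."""
    if not structure.foldable:
        raise ValueError("cannot check anticodon of an unfoldable structure")
    if gene_name not in ANTICODONS:
        raise ValueError(f"unknown tRNA name {gene_name!r}")
    codon = revcomp(structure.anticodon)
    if any(b not in "ACGT" for b in codon):
        return False
    aa = MITO_CODE[codon]
    family = gene_name.split("-")[1]
    aa3 = family.split("(")[0]
    if aa != _AA3_TO_1[aa3]:
        return False
    if family == "Ser(AGY)":
        return codon in ("AGT", "AGC")
    if family == "Ser(UCN)":
        return codon.startswith("TC")
    if family == "Leu(UUR)":
        return codon in ("TTA", "TTG")
    if family == "Leu(CUN)":
        return codon.startswith("CT")
    return True


def cohort_fold_report(genomes, params: FoldParams | None = None):
    """Fold every annotated tRNA of a cohort.

    ``genomes`` is an iterable of (MitoGenome, GenomeAnnotation) pairs.
    Returns a DataFrame with one row per (species, tRNA): fold class, score,
    arm lengths and whether the anticodon matches the gene name.  The
    D-armless model is allowed to compete for every tRNA, so a genuinely
    DHU-armless gene is classified as such wherever it occurs.
    """
    import pandas as pd

    from .genome_model import extract_feature_seq

    rows = []
    for genome, annotation in genomes:
        for feat in annotation.by_kind("tRNA"):
            seq = extract_feature_seq(genome, feat)
            try:
                s = fold_trna(seq, params, allow_no_D=True)
            except ValueError:
                s = CloverleafStructure(model="unfoldable", score=0, sequence=seq)
            rows.append({
                "species": genome.id, "trna": feat.name, "class": s.model,
                "score": s.score, "length": len(seq),
                "d_loop_len": s.arm_length("d_loop") or s.arm_length("d_replacement_loop"),
                "ac_loop_len": s.arm_length("ac_loop"),
                "variable_len": s.arm_length("variable"),
                "t_loop_len": s.arm_length("t_loop"),
                "anticodon": s.anticodon if s.foldable else "",
                "anticodon_ok": (anticodon_check(s, feat.name)
                                 if s.foldable and feat.name in ANTICODONS else False),
            })
    return pd.DataFrame(rows)
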