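"""Nei-Gojobori (1986) synonymous/nonsynonymous substitution estimation.

For each codon the potential synonymous sites are counted as the per-position
fraction of single-nucleotide changes that preserve the amino acid under the
vertebrate mitochondrial code; changes that would create a stop codon are
excluded from the tally and the position renormalized, so every codon still
carries 3 sites in total.  Observed differences between two codons that
differ at more than one position are averaged over all mutational pathways
(orderings of the single changes) with equal weights, excluding pathways that
pass through a stop codon.  Proportions pS = Sd/S and pN = Nd/N are corrected
for multiple hits with the Jukes-Cantor formula

    d = -(3/4) ln(1 - 4p/3),

undefined when p >= 3/4.  The gene-level selection summary is Ka = mean
pairwise dN, Ks = mean pairwise dS, and omega = Ka/Ks (ratio of means, which
stays stable when individual pairwise dS are near zero).  omega < 1 indicates
purifying selection, omega = 1 neutrality, omega > 1 positive selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .alignment_variation import Alignment
from .codon_usage import MITO_CODE, STOP_CODONS

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"
CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]


def _codon_index(codon: str) -> int:
    return (_BASE_INDEX[codon[0]] * 16 + _BASE_INDEX[codon[1]] * 4
            + _BASE_INDEX[codon[2]])


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Potential (synonymous, nonsynonymous) sites of one codon.

    Each position contributes the fraction of its single-nucleotide changes
    that are synonymous, taken over the changes that do not create a stop
    codon; the two fractions always sum to 1 per position, so S + N = 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if any(b not in _BASE_INDEX for b in codon) or len(codon) != 3:
        raise ValueError(f"invalid codon {codon!r}")
    aa = MITO_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = non = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            if MITO_CODE[mutant] == aa:
                syn += 1
            else:
                non += 1
        if syn + non:
            s += syn / (syn + non)
    return s, 3.0 - s


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float, bool]:
    """Average (synonymous, nonsynonymous) differences between two codons
    over all equal-weight mutational pathways avoiding stop codons.

    Returns (sd, nd, valid); valid is False when every pathway passes
    through a stop, in which case the codon pair is skipped entirely.
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0, True
    syn_tot = non_tot = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = ca
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if MITO_CODE[cur] == MITO_CODE[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            syn_tot += syn
            non_tot += non
            n_paths += 1
    if n_paths == 0:
        return 0.0, 0.0, False
    return syn_tot / n_paths, non_tot / n_paths, True


# precomputed lookup tables over all sense-codon pairs
_SITE_S = np.full(64, np.nan)
_SITE_N = np.full(64, np.nan)
for _c in CODONS:
    if _c not in STOP_CODONS:
        _i = _codon_index(_c)
        _SITE_S[_i], _SITE_N[_i] = ng86_site_counts(_c)

_SD = np.zeros((64, 64))
_ND = np.zeros((64, 64))
_VALID = np.zeros((64, 64), dtype=bool)
for _ca in CODONS:
    if _ca in STOP_CODONS:
        continue
    for _cb in CODONS:
        if _cb in STOP_CODONS:
            continue
        _sd, _nd, _ok = _pathway_diffs(_ca, _cb)
        _ia, _ib = _codon_index(_ca), _codon_index(_cb)
        _SD[_ia, _ib], _ND[_ia, _ib], _VALID[_ia, _ib] = _sd, _nd, _ok


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN at or beyond the 3/4 ceiling."""
    if math.isnan(p) or p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class PairwiseKaKs:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    n_codons: int


@dataclass
class KaKsResult:
    gene: str
    Ka: float          # mean pairwise dN
    Ks: float          # mean pairwise dS
    omega: float       # Ka / Ks, NaN when Ks undefined or zero
    n_pairs: int


def encode_codons(seq: str) -> np.ndarray:
    """Codon-index array for one row; -1 marks gapped, ambiguous or stop
    codons, which are skipped pairwise."""
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("codon sequence length not divisible by 3")
    out = np.full(len(seq) // 3, -1, dtype=np.int64)
    for k in range(len(out)):
        codon = seq[3 * k:3 * k + 3]
        if all(b in _BASE_INDEX for b in codon) and codon not in STOP_CODONS:
            out[k] = _codon_index(codon)
    return out


def ng86_pair(codons_a, codons_b) -> PairwiseKaKs:
    """NG86 estimates for one sequence pair.

    Accepts nucleotide strings (length a codon multiple) or pre-encoded
    codon-index arrays.  Site counts are averaged between the two sequences
    over the codons compared; codon pairs whose pathways all cross a stop are
    skipped, as are codons with gaps or ambiguity in either sequence.
    """
    a = encode_codons(codons_a) if isinstance(codons_a, str) else np.asarray(codons_a)
    b = encode_codons(codons_b) if isinstance(codons_b, str) else np.asarray(codons_b)
    if a.shape != b.shape:
        raise ValueError("codon sequences differ in length")
    usable = (a >= 0) & (b >= 0) & _VALID[a.clip(0), b.clip(0)]
    ia, ib = a[usable], b[usable]
    n = int(usable.sum())
    if n == 0:
        nan = float("nan")
        return PairwiseKaKs(nan, nan, 0.0, 0.0, nan, nan, nan, nan, 0)
    S = float((_SITE_S[ia] + _SITE_S[ib]).sum()) / 2.0
    N = float((_SITE_N[ia] + _SITE_N[ib]).sum()) / 2.0
    Sd = float(_SD[ia, ib].sum())
    Nd = float(_ND[ia, ib].sum())
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")
    return PairwiseKaKs(S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
                        dS=jukes_cantor(pS), dN=jukes_cantor(pN), n_codons=n)


def gene_kaks(codon_alignment: Alignment, gene: str = "") -> KaKsResult:
    """Gene-level Ka, Ks and omega over all sequence pairs of an alignment.

    Ka and Ks are means of the defined pairwise dN and dS; omega is their
    ratio (NaN when the aggregate dS is zero or no pair is defined).
    """
    enc = [encode_codons(row) for row in codon_alignment.rows]
    dn, ds = [], []
    n_pairs = 0
    for i in range(len(enc)):
        for j in range(i + 1, len(enc)):
            pair = ng86_pair(enc[i], enc[j])
            if not math.isnan(pair.dN) and not math.isnan(pair.dS):
                dn.append(pair.dN)
                ds.append(pair.dS)
                n_pairs += 1
    if n_pairs == 0:
        nan = float("nan")
        return KaKsResult(gene=gene, Ka=nan, Ks=nan, omega=nan, n_pairs=0)
    ka = sum(dn) / n_pairs
    ks = sum(ds) / n_pairs
    omega = ka / ks if ks > 0 else float("nan")
    return KaKsResult(gene=gene, Ka=ka, Ks=ks, omega=omega, n_pairs=n_pairs)


def kaks_table(results: list[KaKsResult], ndigits: int = 4) -> str:
    lines = ["gene\tKa\tKs\tomega\tn_pairs"]
    for r in results:
        lines.append(f"{r.gene}\t{r.Ka:.{ndigits}f}\t{r.Ks:.{ndigits}f}"
                     f"\t{r.omega:.{ndigits}f}\t{r.n_pairs}")
    return "\n".join(lines) + "\n"
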