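"""Independent brute-force oracles for cross-checking the library.

Everything here is deliberately written from the definitions, not from the
library code: the genetic code comes straight from Biopython's table, the
repeat enumerator scans naively, the fold oracle enumerates partitions with
nested loops, and pathway counting recurses over orderings.  Agreement
between these and the fast implementations is what the oracle tests assert.
"""

from __future__ import annotations

import itertools
import math

import dendropy
from Bio.Data import CodonTable

_T = CodonTable.unambiguous_dna_by_id[2]
CODE = dict(_T.forward_table)
STOPS = set(_T.stop_codons)
for _s in STOPS:
    CODE[_s] = "*"
BASES = "ACGT"


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def site_counts(codon):
    """Potential synonymous sites by direct per-position enumeration."""
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            m = codon[:pos] + b + codon[pos + 1:]
            if m in STOPS:
                continue
            tot += 1
            if CODE[m] == CODE[codon]:
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


def pair_diffs(ca, cb):
    """(sd, nd, n_valid_paths) by recursive enumeration of orderings."""
    positions = [i for i in range(3) if ca[i] != cb[i]]

    def walk(cur, remaining):
        if not remaining:
            return [(0, 0)]
        out = []
        for pos in remaining:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOPS:
                continue
            step = (1, 0) if CODE[cur] == CODE[nxt] else (0, 1)
            for s, n in walk(nxt, [p for p in remaining if p != pos]):
                out.append((step[0] + s, step[1] + n))
        return out

    paths = walk(ca, positions)
    if not paths:
        return 0.0, 0.0, 0
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd, len(paths)


def ng86(seq_a, seq_b):
    """Full NG86 pair estimate (S, N, Sd, Nd, dS, dN) from scratch."""
    S = N = Sd = Nd = 0.0
    for k in range(len(seq_a) // 3):
        ca, cb = seq_a[3 * k:3 * k + 3], seq_b[3 * k:3 * k + 3]
        if (set(ca) | set(cb)) - set(BASES) or ca in STOPS or cb in STOPS:
            continue
        sd, nd, npaths = pair_diffs(ca, cb)
        if npaths == 0:
            continue
        sa, na = site_counts(ca)
        sb, nb = site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += sd
        Nd += nd

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    pS = Sd / S if S else float("nan")
    pN = Nd / N if N else float("nan")
    return S, N, Sd, Nd, jc(pS), jc(pN)


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

def classify(rows):
    """(constant, singleton, pis, excluded) under complete deletion."""
    const = single = pis = excl = 0
    for j in range(len(rows[0])):
        col = [r[j] for r in rows]
        if any(c not in BASES for c in col):
            excl += 1
            continue
        counts = {b: col.count(b) for b in set(col)}
        if len(counts) == 1:
            const += 1
        elif sum(1 for v in counts.values() if v >= 2) >= 2:
            pis += 1
        else:
            single += 1
    return const, single, pis, excl


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def tandem_runs(s, min_period=2, max_period=200, min_copies=2.0, min_span=8):
    """Maximal exact tandem runs by naive per-(start, period) extension,
    then the documented greedy resolution (span desc, period asc, start)."""
    n = len(s)
    cands = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        i = 0
        while i + p < n:
            if s[i] != s[i + p]:
                i += 1
                continue
            j = i
            while j + p < n and s[j] == s[j + p]:
                j += 1
            start, end = i, j + p          # maximal run for this period
            span = end - start
            if span / p >= min_copies and span >= min_span:
                cands.append((start, end, p))
            i = j + 1
    cands.sort(key=lambda c: (-(c[1] - c[0]), c[2], c[0]))
    chosen = []
    for c in cands:
        if all(c[1] <= o[0] or c[0] >= o[1] for o in chosen):
            chosen.append(c)
    return sorted(chosen)


# ---------------------------------------------------------------------------
# tRNA fold
# ---------------------------------------------------------------------------

_PAIRS = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2,
          ("G", "T"): 1, ("T", "G"): 1}


def _score_stem(seq, i0, i1, j0, j1):
    """Score strand seq[i0:i1] against seq[j0:j1] reversed; None if more
    than one mismatch."""
    score, mism = 0, 0
    for k in range(i1 - i0):
        v = _PAIRS.get((seq[i0 + k], seq[j1 - 1 - k]))
        if v is None:
            mism += 1
            if mism > 1:
                return None
        else:
            score += v
    return score


def fold_best(seq, allow_no_D=False):
    """Exhaustive partition enumeration; returns (score, model, dl, v, ts, tl)
    of the winner under the documented tie-break, or None if unfoldable."""
    n = len(seq)
    core = n - 15
    best = None
    for model, ds_range in ((0, (3, 4)), (1, (0,))):
        if model == 1 and not allow_no_D:
            continue
        for ds in ds_range:
            for dl in range(4, 13):
                for ts in (4, 5):
                    for tl in range(5, 10):
                        v = core - (2 * ds + dl) - 17 - (2 * ts + tl)
                        if not 3 <= v <= 23:
                            continue
                        acc = _score_stem(seq, 0, 7, n - 8, n - 1)
                        if acc is None:
                            continue
                        total = acc
                        pos = 7
                        if model == 0:
                            dsc = _score_stem(seq, pos, pos + ds,
                                              pos + ds + dl, pos + 2 * ds + dl)
                            if dsc is None:
                                continue
                            total += dsc
                            pos += 2 * ds + dl
                        else:
                            pos += dl
                        acs = _score_stem(seq, pos, pos + 5, pos + 12, pos + 17)
                        if acs is None:
                            continue
                        total += acs
                        pos += 17 + v
                        tsc = _score_stem(seq, pos, pos + ts,
                                          pos + ts + tl, pos + 2 * ts + tl)
                        if tsc is None:
                            continue
                        total += tsc
                        key = (-total, model, dl, v, ts, tl)
                        if best is None or key < best:
                            best = key
    if best is None:
        return None
    return (-best[0], "cloverleaf" if best[1] == 0 else "D-armless",
            best[2], best[3], best[4], best[5])


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n, bl_range=(0.05, 1.0)):
    """Random binary topology with strictly positive branch lengths; returns
    (newick, labels, distance matrix) where distances are leaf path sums."""
    labels = [f"s{i:02d}" for i in range(n)]
    nodes = [(lbl, {lbl: 0.0}) for lbl in labels]  # (newick, leaf depth map)

    def draw():
        return float(rng.uniform(*bl_range))

    parts = []
    for nwk, depths in nodes:
        bl = draw()
        parts.append((f"{nwk}:{bl:.6f}", {k: v + bl for k, v in depths.items()}))
    nodes = parts
    dist = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nw1, d1), (nw2, d2) = nodes[i], nodes[j]
        for a, da in d1.items():
            for b, db in d2.items():
                dist[frozenset((a, b))] = da + db
        if len(nodes) == 2:
            nodes = [(f"({nw1},{nw2});", {})]
            break
        bl = draw()
        merged = {k: v + bl for k, v in (d1 | d2).items()}
        nodes = ([x for k, x in enumerate(nodes) if k not in (i, j)]
                 + [(f"({nw1},{nw2}):{bl:.6f}", merged)])
    import numpy as np
    mat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            mat[a, b] = mat[b, a] = dist[frozenset((labels[a], labels[b]))]
    return nodes[0][0], labels, mat


def rf_distance(newick_a, newick_b):
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.is_rooted = tb.is_rooted = False
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


def bipartition_sides(newick):
    """All leaf-label bipartition sides of a tree, by direct enumeration."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    sides = {leaves}
    for node in tree.preorder_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        sides.add(below)
        sides.add(leaves - below)
    return sides
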