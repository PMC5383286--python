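"""Alignment site classification, p-distances and neighbor-joining plumbing.

Per-gene multiple alignments are summarized by the standard site categories:
a column is *constant* when it shows one state, *parsimony-informative* (PIS)
when at least two states are each present in at least two sequences, and a
*singleton* when it is variable but not parsimony-informative (so
``variable = singleton + PIS`` always).  Uncorrected pairwise distances
(p-distances, mismatches over compared sites) quantify per-gene rate
heterogeneity; a neighbor-joining tree over those distances provides the
qualitative topology checks used downstream (NJ recovers additive distances
exactly, which also makes it its own best test oracle).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO

logger = logging.getLogger("mitocomp")

ALPHABET = set("ACGTN-")
_BASES = set("ACGT")


@dataclass
class Alignment:
    """Labeled equal-length rows over {A,C,G,T,N,-}."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        bad = set("".join(self.rows)) - ALPHABET
        if bad:
            raise ValueError(f"disallowed alignment characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n(self) -> int:
        return len(self.rows)


def read_alignment(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    return Alignment(labels=[r.id for r in records],
                     rows=[str(r.seq) for r in records])


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for label, row in zip(aln.labels, aln.rows):
            fh.write(f">{label}\n{row}\n")


@dataclass
class SiteSummary:
    n_constant: int
    n_variable: int
    n_singleton: int
    n_parsimony_informative: int
    n_excluded: int
    analyzed: int = field(init=False)

    def __post_init__(self) -> None:
        self.analyzed = self.n_constant + self.n_variable

    def _pct(self, x: int) -> float:
        return 100.0 * x / self.analyzed if self.analyzed else float("nan")

    @property
    def pct_variable(self) -> float:
        return self._pct(self.n_variable)

    @property
    def pct_pis(self) -> float:
        return self._pct(self.n_parsimony_informative)

    @property
    def pct_singleton(self) -> float:
        return self._pct(self.n_singleton)


@dataclass
class DistanceResult:
    """Symmetric p-distance matrix with zero diagonal; ``average`` is the
    mean of defined off-diagonal upper-triangle entries."""

    labels: list[str]
    matrix: np.ndarray

    @property
    def average(self) -> float:
        iu = np.triu_indices(len(self.labels), k=1)
        vals = self.matrix[iu]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")


def _analyzed_columns(aln: Alignment, deletion_policy: str):
    cols = ["".join(row[j] for row in aln.rows) for j in range(aln.length)]
    if deletion_policy == "complete":
        kept = [c for c in cols if set(c) <= _BASES]
    elif deletion_policy == "pairwise":
        kept = [c for c in cols if sum(ch in _BASES for ch in c) >= 1]
    else:
        raise ValueError(f"unknown deletion policy {deletion_policy!r}")
    return cols, kept


def classify_sites(aln: Alignment, deletion_policy: str = "complete") -> SiteSummary:
    """Count constant / singleton / parsimony-informative columns.

    Under the default complete-deletion policy any column containing a gap or
    N is excluded before classification; under ``pairwise`` only the missing
    characters within a column are ignored.
    """
    cols, kept = _analyzed_columns(aln, deletion_policy)
    if not kept:
        raise ValueError("all columns excluded by deletion policy")
    n_const = n_single = n_pis = 0
    for col in kept:
        counts: dict[str, int] = {}
        for ch in col:
            if ch in _BASES:
                counts[ch] = counts.get(ch, 0) + 1
        if len(counts) <= 1:
            n_const += 1
        elif sum(1 for v in counts.values() if v >= 2) >= 2:
            n_pis += 1
        else:
            n_single += 1
    return SiteSummary(n_constant=n_const, n_variable=n_single + n_pis,
                       n_singleton=n_single, n_parsimony_informative=n_pis,
                       n_excluded=len(cols) - len(kept))


def p_distance(aln: Alignment, deletion_policy: str = "complete") -> DistanceResult:
    """Uncorrected pairwise distances: mismatches / compared sites.

    Complete deletion first drops every column containing a gap or N and
    compares the remainder; pairwise deletion compares, per pair, the sites
    where both sequences have a plain base.  A pair with no comparable sites
    gets a missing (NaN) entry with a warning.
    """
    n = aln.n
    arr = np.frombuffer("".join(aln.rows).encode(), dtype="S1").reshape(n, aln.length)
    is_base = np.isin(arr, [b"A", b"C", b"G", b"T"])
    if deletion_policy == "complete":
        keep = is_base.all(axis=0)
        arr, is_base = arr[:, keep], is_base[:, keep]
    elif deletion_policy != "pairwise":
        raise ValueError(f"unknown deletion policy {deletion_policy!r}")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = is_base[i] & is_base[j]
            m = int(both.sum())
            if m == 0:
                logger.warning("no comparable sites for pair (%s, %s)",
                               aln.labels[i], aln.labels[j])
                mat[i, j] = mat[j, i] = np.nan
                continue
            diff = int((arr[i][both] != arr[j][both]).sum())
            mat[i, j] = mat[j, i] = diff / m
    return DistanceResult(labels=list(aln.labels), matrix=mat)


def distance_table(dist: DistanceResult, ndigits: int = 4) -> str:
    """Square matrix in the PHYLIP-style layout (count line, then rows)."""
    lines = [str(len(dist.labels))]
    for label, row in zip(dist.labels, dist.matrix):
        lines.append(label + "\t" + "\t".join(f"{v:.{ndigits}f}" for v in row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: DistanceResult) -> str:
    """Neighbor-joining tree (unrooted, Newick with branch lengths).

    Standard Q-criterion agglomeration; equal Q values are broken
    deterministically by the lexicographic order of the pair's smallest
    member labels, so reruns are byte-identical.  Requires a complete matrix
    and at least three taxa.
    """
    if np.isnan(dist.matrix).any():
        raise ValueError("distance matrix has missing entries")
    n0 = len(dist.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    # active nodes: newick subtree string + sort key (smallest leaf label)
    nodes = [(lbl, lbl) for lbl in dist.labels]
    d = {(i, j): float(dist.matrix[i, j]) for i in range(n0) for j in range(n0)}
    active = list(range(n0))
    next_id = n0

    def D(a, b):
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    nodes = {i: nodes[i] for i in range(n0)}
    while len(active) > 3:
        m = len(active)
        r = {a: sum(D(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * D(a, b) - r[a] - r[b]
                key = (q, min(nodes[a][1], nodes[b][1]), max(nodes[a][1], nodes[b][1]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = D(a, b)
        ba = dab / 2 + (r[a] - r[b]) / (2 * (m - 2))
        bb = dab - ba
        ba, bb = max(ba, 0.0), max(bb, 0.0)
        new = next_id
        next_id += 1
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = (D(a, c) + D(b, c) - dab) / 2
        nodes[new] = (f"({nodes[a][0]}:{ba:.10g},{nodes[b][0]}:{bb:.10g})",
                      min(nodes[a][1], nodes[b][1]))
        active = [c for c in active if c not in (a, b)] + [new]

    x, y, z = sorted(active, key=lambda c: nodes[c][1])
    bx = (D(x, y) + D(x, z) - D(y, z)) / 2
    by = (D(x, y) + D(y, z) - D(x, z)) / 2
    bz = (D(x, z) + D(y, z) - D(x, y)) / 2
    bx, by, bz = (max(v, 0.0) for v in (bx, by, bz))
    return (f"({nodes[x][0]}:{bx:.10g},{nodes[y][0]}:{by:.10g},"
            f"{nodes[z][0]}:{bz:.10g});")


def check_monophyly(newick: str, label_set) -> bool:
    """True iff ``label_set`` is one side of a bipartition of the tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    labels = set(label_set)
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = labels - leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if labels == leaves or len(labels) == 1:
        return True
    for node in tree.preorder_node_iter():
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below == labels or leaves - below == labels:
            return True
    return False
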