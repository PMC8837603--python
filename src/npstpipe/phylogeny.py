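"""Progressive alignment, neighbor-joining trees and novel-clade calling.

The scientific content here is the clade logic: any maximal clade (edge
bipartition side) containing at least two metagenome-derived sequence tags
and no characterized reference is flagged as a candidate novel family.
The aligner is a deterministic progressive implementation — adequate for
p-distance screening, not a general-purpose MSA replacement; a precomputed
alignment can be supplied instead.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

import dendropy

_GAP_PENALTY = 2.0
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}


@dataclass
class LabeledAlignment:
    rows: list  # (label, aligned_seq)
    label_class: dict  # label -> "reference" | "npst"

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")


@dataclass
class CladeCall:
    clade_leaves: frozenset
    is_novel: bool
    support_note: str = ""


class DistanceError(ValueError):
    """A sequence pair shares no ungapped columns."""


# ---------------------------------------------------------------------------
# progressive alignment

def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(5, L) per-column character frequencies over A,C,G,T,-."""
    n = len(rows)
    L = len(rows[0])
    freqs = np.zeros((5, L))
    for row in rows:
        idx = np.fromiter((_NT_INDEX.get(c, 4) for c in row), dtype=np.int64, count=L)
        np.add.at(freqs, (idx, np.arange(L)), 1.0)
    return freqs / n


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global DP merge of two profiles (match +1 / mismatch -1 / gap -2).

    Linear gap costs allow the inner maximization to be computed with a
    prefix-scan, so the DP runs row-by-row on numpy vectors.
    """
    fa, fb = _profile_freqs(rows_a), _profile_freqs(rows_b)
    la, lb = fa.shape[1], fb.shape[1]
    xa, xb = fa[:4], fb[:4]
    ga, gb = fa[4], fb[4]
    sa, sb = xa.sum(axis=0), xb.sum(axis=0)
    g = _GAP_PENALTY

    H = np.empty((la + 1, lb + 1))
    H[0, :] = -g * np.arange(lb + 1)
    H[:, 0] = -g * np.arange(la + 1)
    jj = np.arange(lb + 1, dtype=float)
    for i in range(1, la + 1):
        match = xa[:, i - 1] @ xb            # (lb,)
        tot = sa[i - 1] * sb
        score = 2.0 * match - tot - g * (ga[i - 1] * sb + gb * sa[i - 1])
        M = np.empty(lb + 1)
        M[0] = H[i, 0]
        M[1:] = np.maximum(H[i - 1, :-1] + score, H[i - 1, 1:] - g)
        H[i] = np.maximum.accumulate(M + g * jj) - g * jj

    # traceback
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = la, lb
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            match = float(xa[:, i - 1] @ xb[:, j - 1])
            tot = sa[i - 1] * sb[j - 1]
            score = 2.0 * match - tot - g * (ga[i - 1] * sb[j - 1] + gb[j - 1] * sa[i - 1])
            if abs(H[i, j] - (H[i - 1, j - 1] + score)) < eps:
                for r, row in enumerate(rows_a):
                    out_a[r].append(row[i - 1])
                for r, row in enumerate(rows_b):
                    out_b[r].append(row[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and abs(H[i, j] - (H[i - 1, j] - g)) < eps:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i - 1])
            for r in range(len(rows_b)):
                out_b[r].append("-")
            i -= 1
            continue
        for r in range(len(rows_a)):
            out_a[r].append("-")
        for r, row in enumerate(rows_b):
            out_b[r].append(row[j - 1])
        j -= 1
    return ["".join(reversed(c)) for c in out_a], ["".join(reversed(c)) for c in out_b]


def _kmer_distance(a: str, b: str, k: int = 4) -> float:
    k = min(k, len(a), len(b))
    if k == 0:
        return 1.0
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    union = ka | kb
    return 1.0 - len(ka & kb) / len(union) if union else 0.0


def align_progressive(seqs: list, label_class: dict | None = None) -> LabeledAlignment:
    """Deterministic progressive alignment of labeled sequences.

    ``seqs`` is a list of (label, sequence). The guide tree is average-link
    clustering on k-mer Jaccard distances; merges are pairwise global
    profile alignments. Input order does not matter: rows are processed and
    returned sorted by label.
    """
    if len(seqs) < 2:
        raise ValueError("align_progressive requires at least 2 sequences")
    ordered = sorted(seqs, key=lambda t: t[0])
    labels = [lab for lab, _ in ordered]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    seqs_up = [(lab, s.upper()) for lab, s in ordered]

    n = len(seqs_up)
    if n == 2:
        merged_a, merged_b = _align_profiles([seqs_up[0][1]], [seqs_up[1][1]])
        rows = [(labels[0], merged_a[0]), (labels[1], merged_b[0])]
        return LabeledAlignment(rows, dict(label_class or {}))

    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = _kmer_distance(seqs_up[i][1], seqs_up[j][1])
    Z = linkage(squareform(dmat, checks=False), method="average")

    # cluster index -> (labels, aligned rows)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([labels[i]], [seqs_up[i][1]]) for i in range(n)
    }
    for step, (ia, ib, _, _) in enumerate(Z):
        la, ra = clusters.pop(int(ia))
        lb, rb = clusters.pop(int(ib))
        if la[0] > lb[0]:  # deterministic operand order
            la, ra, lb, rb = lb, rb, la, ra
        ma, mb = _align_profiles(ra, rb)
        clusters[n + step] = (la + lb, ma + mb)
    _, (final_labels, final_rows) = clusters.popitem()
    by_label = dict(zip(final_labels, final_rows))
    rows = [(lab, by_label[lab]) for lab in labels]
    return LabeledAlignment(rows, dict(label_class or {}))


# ---------------------------------------------------------------------------
# distances and neighbor joining

def p_distance_matrix(aln: LabeledAlignment) -> tuple[list, np.ndarray]:
    """Pairwise mismatch fraction with pairwise deletion of gap columns."""
    labels = [lab for lab, _ in aln.rows]
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for _, s in aln.rows]
    gap = ord("-")
    n = len(labels)
    D = np.zeros((n, n))
    bad_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            both = (arrs[i] != gap) & (arrs[j] != gap)
            shared = int(both.sum())
            if shared == 0:
                bad_pairs.append((labels[i], labels[j]))
                continue
            mism = int((arrs[i][both] != arrs[j][both]).sum())
            D[i, j] = D[j, i] = mism / shared
    if bad_pairs:
        raise DistanceError(f"no shared ungapped columns for pairs: {bad_pairs}")
    return labels, D


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def nj_tree(aln: LabeledAlignment) -> str:
    """Neighbor-joining on p-distances, returned as an unrooted Newick string."""
    if len(aln.rows) < 3:
        raise ValueError("nj_tree requires at least 3 rows")
    labels, D = p_distance_matrix(aln)
    return nj_from_distances(labels, D)


def nj_from_distances(labels: list, D: np.ndarray) -> str:
    """Neighbor-joining on an explicit distance matrix.

    Tie-breaking in the Q-matrix minimization is by the label-sorted pair,
    making the output deterministic.
    """
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    # active node -> (newick fragment, sort key = min leaf label)
    nodes = {i: (labels[i], labels[i]) for i in range(len(labels))}
    dist = {(i, j): D[i, j] for i in range(len(labels)) for j in range(len(labels))}
    next_id = len(labels)
    active = sorted(nodes)

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    while len(active) > 3:
        n_act = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(n_act):
            for bj in range(ai + 1, n_act):
                i, j = active[ai], active[bj]
                q = (n_act - 2) * d(i, j) - r[i] - r[j]
                key = tuple(sorted((nodes[i][1], nodes[j][1])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2.0 * (n_act - 2))
        lj = d(i, j) - li
        children = sorted(
            [(nodes[i][1], nodes[i][0], li), (nodes[j][1], nodes[j][0], lj)]
        )
        frag = "(" + ",".join(f"{nk}:{_fmt(ln)}" for _, nk, ln in children) + ")"
        new = next_id
        next_id += 1
        nodes[new] = (frag, children[0][0])
        for k in active:
            if k in (i, j):
                continue
            dist[(min(new, k), max(new, k))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        active = sorted(k for k in active if k not in (i, j)) + [new]
        active.sort()

    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    parts = sorted(
        [(nodes[a][1], nodes[a][0], la), (nodes[b][1], nodes[b][0], lb), (nodes[c][1], nodes[c][0], lc)]
    )
    return "(" + ",".join(f"{nk}:{_fmt(ln)}" for _, nk, ln in parts) + ");"


# ---------------------------------------------------------------------------
# novel clade calling

def call_novel_clades(newick: str, label_class: dict) -> list[CladeCall]:
    """Maximal reference-free bipartition sides with >= 2 NPST leaves.

    Every internal edge of the (unrooted) tree splits the leaves into two
    sides; a side is a candidate when it contains no ``reference`` leaf and
    at least two ``npst`` leaves, and is not contained in a larger such
    side.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    leaves = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
    if any(lab is None for lab in leaves):
        raise ValueError("tree has unlabeled leaves")
    unknown = sorted(set(leaves) - set(label_class))
    if unknown:
        raise ValueError(f"leaves without a label class: {unknown}")
    all_leaves = frozenset(leaves)

    sides: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        under = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        if 0 < len(under) < len(all_leaves):
            sides.add(under)
            sides.add(all_leaves - under)

    candidates = [
        s
        for s in sides
        if all(label_class[lab] != "reference" for lab in s)
        and sum(1 for lab in s if label_class[lab] == "npst") >= 2
    ]
    maximal = [
        s for s in candidates if not any(s < other for other in candidates)
    ]
    calls = [
        CladeCall(
            clade_leaves=s,
            is_novel=True,
            support_note=f"{len(s)} leaves, no reference leaf on this side",
        )
        for s in maximal
    ]
    calls.sort(key=lambda c: sorted(c.clade_leaves))
    return calls
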