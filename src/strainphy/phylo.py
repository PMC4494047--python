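"""Distance-based phylogenetics: K2P distances, neighbor joining, bootstrap.

The Kimura 2-parameter distance distinguishes transitions (A<->G, C<->T,
observed fraction P) from transversions (fraction Q) and corrects for
multiple hits:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Trees are built by the Saitou-Nei neighbor-joining agglomeration, which is
exact on additive distance matrices. Bootstrap support for an internal edge
is the percentage of column-resampled replicates whose NJ tree contains the
same leaf bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

__all__ = [
    "SaturationError",
    "DistanceMatrix",
    "k2p_distance",
    "k2p_matrix",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "compare_trees",
]

_TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_MISSING = frozenset("N-.?")


class SaturationError(ValueError):
    """Raised when observed divergence exceeds the K2P correctable range."""


@dataclass
class DistanceMatrix:
    """Symmetric strain-by-strain distance matrix with a source tag."""

    ids: list[str]
    data: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.data, self.data.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("distance matrix has non-finite entries")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    return arr


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """K2P distance between two equal-length sequences, pairwise deletion of N."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    valid = np.ones(len(a), dtype=bool)
    for ch in _MISSING:
        cb = ch.encode()
        valid &= (a != cb) & (b != cb)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable sites after removing missing data")
    a, b = a[valid], b[valid]
    diff = a != b
    # transitions: purine<->purine or pyrimidine<->pyrimidine
    purine = (a == b"A") | (a == b"G")
    purine_b = (b == b"A") | (b == b"G")
    ts = diff & (purine == purine_b)
    p = float(ts.sum()) / n
    q = float(diff.sum() - ts.sum()) / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P saturation: P={p:.4f}, Q={q:.4f} exceed the correctable range"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def _pairwise_counts(mat: np.ndarray, valid: np.ndarray, i: int, j: int):
    v = valid[i] & valid[j]
    n = int(v.sum())
    if n == 0:
        return 0, 0, 0
    a, b = mat[i, v], mat[j, v]
    diff = a != b
    ts = diff & ((a % 2) == (b % 2))  # codes chosen so parity marks purine class
    return n, int(ts.sum()), int(diff.sum() - ts.sum())


# nucleotide codes with A,G even (purines) and C,T odd so transitions keep parity
_CODE = {"A": 0, "G": 2, "C": 1, "T": 3}


def _encode_alignment(seqs: dict[str, str]):
    ids = list(seqs)
    length = len(next(iter(seqs.values())))
    mat = np.zeros((len(ids), length), dtype=np.int8)
    valid = np.zeros((len(ids), length), dtype=bool)
    for r, sid in enumerate(ids):
        s = seqs[sid].upper()
        if len(s) != length:
            raise ValueError("alignment sequences differ in length")
        arr = np.frombuffer(s.encode(), dtype="S1")
        for base, code in _CODE.items():
            m = arr == base.encode()
            mat[r, m] = code
            valid[r] |= m
    return ids, mat, valid


def k2p_matrix(seqs: dict[str, str], source: str = "snp") -> DistanceMatrix:
    """All-pairs K2P distances; saturation aborts naming the strain pair."""
    ids, mat, valid = _encode_alignment(seqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            nn, ts, tv = _pairwise_counts(mat, valid, i, j)
            if nn == 0:
                raise ValueError(f"no comparable sites between {ids[i]} and {ids[j]}")
            p, q = ts / nn, tv / nn
            w1, w2 = 1 - 2 * p - q, 1 - 2 * q
            if w1 <= 0 or w2 <= 0:
                raise SaturationError(
                    f"K2P saturation between strains {ids[i]!r} and {ids[j]!r}"
                )
            d[i, j] = d[j, i] = -0.5 * math.log(w1 * math.sqrt(w2))
    return DistanceMatrix(ids=ids, data=d, source=source)


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; ties broken by lexicographically smallest
    pair of cluster labels; negative branch lengths clamped to zero."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 strains")
    d = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=s) for s in dm.ids]
    labels = list(dm.ids)  # label of each active cluster, for tie-breaking
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        qmat = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qmat, np.inf)
        qmin = qmat.min()
        # deterministic tie-break: smallest (label_i, label_j) among minima
        cand = np.argwhere(np.isclose(qmat, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((labels[active[i]], labels[active[j]]))), i, j)
            for i, j in cand
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # distances from new node u to remaining k
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    # join the final three clusters at an unrooted trifurcation
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    return root


# ---------------------------------------------------------------------------
# Bipartitions, Robinson-Foulds, bootstrap

def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each canonicalized to the side that
    excludes a fixed reference leaf (the lexicographically smallest)."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    all_set = frozenset(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_set - side
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def is_group_monophyletic(tree: TreeNode, names) -> bool:
    """Whether the named leaves form a clade (unrooted sense: the tree has
    an edge separating exactly these leaves from the rest)."""
    leaves = {t.name for t in tree.tips()}
    g = frozenset(names)
    if not g <= leaves:
        raise ValueError("group contains unknown leaves")
    if len(g) <= 1 or len(leaves - g) <= 1:
        return True
    ref = min(leaves)
    side = g if ref not in g else frozenset(leaves - g)
    return side in bipartitions(tree)


def group_support(tree: TreeNode, names) -> int | None:
    """Bootstrap support (0-100) of the edge splitting the named leaves from
    the rest, or None when the tree has no such edge."""
    g = frozenset(names)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if side == g or side == frozenset(t.name for t in tree.tips()) - g:
            return int(node.name) if node.name is not None else None
    return None


def compare_trees(t1: TreeNode, t2: TreeNode) -> tuple[int, list[frozenset[str]]]:
    """Robinson-Foulds distance and list of shared internal bipartitions."""
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    rf = len(b1 ^ b2)
    return rf, sorted(b1 & b2, key=lambda s: (len(s), sorted(s)))


def bootstrap_support(
    seqs: dict[str, str],
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    source: str = "snp",
) -> tuple[TreeNode, int]:
    """NJ tree from the full alignment with bootstrap support on internal nodes.

    Columns are resampled with replacement per replicate; replicates whose
    K2P matrix saturates are skipped and counted. Support values (0-100,
    rounded to nearest integer) are stored as internal node names. Returns
    (tree, n_failed_replicates).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids, mat, valid = _encode_alignment(seqs)
    length = mat.shape[1]
    if length < 1:
        raise ValueError("alignment has no columns")

    def matrix_from(cols: np.ndarray) -> DistanceMatrix:
        sub_seqs = {}
        dec = np.array([b"A", b"C", b"G", b"T"])
        for r, sid in enumerate(ids):
            chars = dec[mat[r, cols]]
            chars = np.where(valid[r, cols], chars, b"N")
            sub_seqs[sid] = b"".join(chars).decode()
        return k2p_matrix(sub_seqs, source=source)

    full_tree = nj_tree(k2p_matrix({s: seqs[s] for s in ids}, source=source))
    target = {bp: 0 for bp in bipartitions(full_tree)}
    failed = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        try:
            rep_tree = nj_tree(matrix_from(cols))
        except (SaturationError, ValueError):
            failed += 1
            continue
        for bp in bipartitions(rep_tree):
            if bp in target:
                target[bp] += 1
    if failed > n_reps / 2:
        raise RuntimeError(
            f"bootstrap aborted: {failed}/{n_reps} replicates failed (saturation)"
        )
    ok = n_reps - failed
    leaves_all = frozenset(t.name for t in full_tree.tips())
    ref = min(leaves_all)
    for node in full_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves_all - side
        if side in target:
            node.name = str(round(100.0 * target[side] / ok)) if ok else "0"
    return full_tree, failed
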