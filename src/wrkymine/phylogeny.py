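"""Native distance phylogenetics: affine-gap alignment, progressive MSA,
p-distances, Saitou–Nei neighbor joining, UPGMA, and bootstrap supports.

Neighbor joining uses the Studier–Keppler Q criterion
``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` and is fully deterministic: ties on Q
are broken by the lexicographically smallest pair of cluster labels (each
cluster labelled by its smallest leaf).  Negative branch lengths are clamped
to zero with the deficit transferred to the sibling branch, preserving the
path length between the joined pair.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord

# ---------------------------------------------------------------------------
# Tree


@dataclass
class Node:
    label: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted representation of an (optionally unrooted) phylogeny.

    An unrooted tree is canonicalized as a trifurcating root.  Supports are
    integer bootstrap percentages attached to internal nodes.
    """

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    # -- serialization -----------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(node.support)
            return f"({inner}){label}:{node.length:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label};"
        inner = ",".join(fmt(c) for c in self.root.children)
        label = "" if self.root.support is None else str(self.root.support)
        return f"({inner}){label};"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        tokens = re.findall(r"\(|\)|,|;|[^(),;]+", text.strip())
        pos = 0

        def parse_node() -> Node:
            nonlocal pos
            node = Node()
            if tokens[pos] == "(":
                pos += 1
                node.children.append(parse_node())
                while tokens[pos] == ",":
                    pos += 1
                    node.children.append(parse_node())
                if tokens[pos] != ")":
                    raise ValueError("unbalanced parentheses in Newick")
                pos += 1
            if pos < len(tokens) and tokens[pos] not in "(),;":
                tok = tokens[pos]
                pos += 1
                label, _, length = tok.partition(":")
                if label:
                    if node.children and label.isdigit():
                        node.support = int(label)
                    else:
                        node.label = label
                if length:
                    node.length = float(length)
            return node

        root = parse_node()
        if tokens[pos] != ";":
            raise ValueError("Newick text must end with ';'")
        return cls(root)

    # -- topology ----------------------------------------------------------
    def _leafsets(self) -> dict[int, frozenset[str]]:
        sets: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[id(node)] = frozenset([node.label])
            else:
                s: set[str] = set()
                for c in node.children:
                    s |= sets[id(c)]
                sets[id(node)] = frozenset(s)
        return sets

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial bipartitions induced by internal edges (unrooted view)."""
        sets = self._leafsets()
        all_leaves = sets[id(self.root)]
        out = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = sets[id(node)]
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset([side, other]))
        return out

    def patristic_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths, keyed by ordered label pairs (both orders)."""
        # distance(i,j) = depth(i) + depth(j) - 2*depth(lca)
        dist: dict[tuple[str, str], float] = {}
        below: dict[int, list[tuple[str, float]]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = [(node.label, node.length)]
                dist[(node.label, node.label)] = 0.0
                continue
            merged: list[tuple[str, float]] = []
            kids = [below[id(c)] for c in node.children]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for la, da in kids[a]:
                        for lb, db in kids[b]:
                            d = da + db
                            dist[(la, lb)] = dist[(lb, la)] = d
            for kid in kids:
                merged.extend((l, d + node.length) for l, d in kid)
            below[id(node)] = merged
        return dist

    def path_length_matrix(self) -> "DistanceMatrix":
        labels = sorted(self.leaf_labels())
        pat = self.patristic_distances()
        n = len(labels)
        m = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    m[i, j] = pat[(a, b)]
        return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# Alignment containers


@dataclass
class Alignment:
    """Equal-length gapped sequence records ('-' is the gap symbol)."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs >= 2 records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal alignment lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def column_subset(self, indices) -> "Alignment":
        recs = [SequenceRecord(r.id, "".join(r.residues[i] for i in indices),
                               r.alphabet, r.description) for r in self.records]
        return Alignment(recs)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("shape mismatch with labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_phylip(self) -> str:
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "  " + "  ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Substitution matrices

_BLOSUM62 = None


def blosum62() -> dict[tuple[str, str], float]:
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices
        mat = substitution_matrices.load("BLOSUM62")
        _BLOSUM62 = {(a, b): float(mat[a, b])
                     for a in mat.alphabet for b in mat.alphabet}
    return _BLOSUM62


# ---------------------------------------------------------------------------
# Pairwise affine-gap global alignment (Gotoh)

_M, _X, _Y = 0, 1, 2  # diagonal / gap-in-b (up) / gap-in-a (left)
_NEG = float("-inf")


def pairwise_global_align(a: str | SequenceRecord, b: str | SequenceRecord,
                          substitution_matrix: dict | None = None,
                          gap_open: float = -10.0, gap_extend: float = -1.0
                          ) -> tuple[str, str, float]:
    """Optimal global alignment with affine gaps; returns (aligned_a,
    aligned_b, score).

    A gap of length k scores ``gap_open + (k-1)*gap_extend``.  Traceback is
    deterministic, preferring diagonal > up > left at ties.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    sub = substitution_matrix if substitution_matrix is not None else blosum62()
    n, m = len(sa), len(sb)

    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend

    for i in range(1, n + 1):
        ca = sa[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi, Yi1 = Y[i], Y[i - 1]
        for j in range(1, m + 1):
            s = sub[(ca, sb[j - 1])]
            Mi[j] = s + max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Xi[j] = max(Mi1[j] + gap_open, Xi1[j] + gap_extend,
                        Yi1[j] + gap_open)
            Yi[j] = max(Mi[j - 1] + gap_open, Yi[j - 1] + gap_extend,
                        Xi[j - 1] + gap_open)

    # traceback, diagonal > up > left at ties
    i, j = n, m
    state = max((_M, _X, _Y), key=lambda st: (M, X, Y)[st][i][j])
    score = (M, X, Y)[state][i][j]
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == _M:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            prev = M[i][j] - sub[(sa[i - 1], sb[j - 1])]
            i, j = i - 1, j - 1
            for st, mat in ((_M, M), (_X, X), (_Y, Y)):
                if math.isclose(mat[i][j], prev, rel_tol=0, abs_tol=1e-9) or \
                        mat[i][j] == prev:
                    state = st
                    break
        elif state == _X:
            out_a.append(sa[i - 1])
            out_b.append("-")
            val = X[i][j]
            i -= 1
            if M[i][j] + gap_open == val:
                state = _M
            elif X[i][j] + gap_extend == val:
                state = _X
            else:
                state = _Y
        else:
            out_a.append("-")
            out_b.append(sb[j - 1])
            val = Y[i][j]
            j -= 1
            if M[i][j] + gap_open == val:
                state = _M
            elif Y[i][j] + gap_extend == val:
                state = _Y
            else:
                state = _X
        if i == 0 and j == 0:
            break
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Identity over aligned columns where neither sequence is gapped, in %."""
    pairs = [(x, y) for x, y in zip(aligned_a, aligned_b)
             if x != "-" and y != "-"]
    if not pairs:
        raise ValueError("no comparable columns")
    return 100.0 * sum(x == y for x, y in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# Progressive multiple alignment

_AA = "ACDEFGHIKLMNPQRSTVWYXBZ"
_AA_INDEX = {c: i for i, c in enumerate(_AA)}


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile_from_rows(rows: list[str]) -> np.ndarray:
    """(n_columns, len(_AA)) frequency profile; gaps contribute no mass."""
    n_col = len(rows[0])
    prof = np.zeros((n_col, len(_AA)))
    for row in rows:
        for j, c in enumerate(row):
            if c != "-":
                prof[j, _AA_INDEX.get(c, _AA_INDEX["X"])] += 1
    totals = prof.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1
    return prof / totals


def _profile_align(rows_a: list[str], rows_b: list[str],
                   submat: np.ndarray, gap_open: float, gap_extend: float
                   ) -> tuple[list[str], list[str]]:
    """Global affine profile–profile alignment; returns gapped row groups."""
    pa = _profile_from_rows(rows_a)
    pb = _profile_from_rows(rows_b)
    S = pa @ submat @ pb.T  # expected substitution score per column pair
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    X[1:, 0] = gap_open + np.arange(n) * gap_extend
    Y[0, 1:] = gap_open + np.arange(m) * gap_extend
    for i in range(1, n + 1):
        Mprev, Xprev, Yprev = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        best_prev = np.maximum(np.maximum(Mprev, Xprev), Yprev)
        Xi[1:] = np.maximum(Mprev[1:] + gap_open,
                            np.maximum(Xprev[1:] + gap_extend,
                                       Yprev[1:] + gap_open))
        row_s = S[i - 1]
        for j in range(1, m + 1):
            Mi[j] = row_s[j - 1] + best_prev[j - 1]
            Yi[j] = max(Mi[j - 1] + gap_open, Yi[j - 1] + gap_extend,
                        Xi[j - 1] + gap_open)
    i, j = n, m
    state = max((_M, _X, _Y), key=lambda st: (M, X, Y)[st][i, j])
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == _M and i > 0 and j > 0:
            ops.append("D")
            prev = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for st, mat in ((_M, M), (_X, X), (_Y, Y)):
                if abs(mat[i, j] - prev) < 1e-9:
                    state = st
                    break
        elif state == _X or (state == _M and j == 0):
            ops.append("U")
            val = X[i, j]
            i -= 1
            state = (_M if abs(M[i, j] + gap_open - val) < 1e-9 else
                     _X if abs(X[i, j] + gap_extend - val) < 1e-9 else _Y)
        else:
            ops.append("L")
            val = Y[i, j]
            j -= 1
            state = (_M if abs(M[i, j] + gap_open - val) < 1e-9 else
                     _Y if abs(Y[i, j] + gap_extend - val) < 1e-9 else _X)
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in "DU":
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            ia += 1
        else:
            for r in out_a:
                r.append("-")
        if op in "DL":
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ib += 1
        else:
            for r in out_b:
                r.append("-")
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(records: list[SequenceRecord],
                    gap_open: float = -10.0, gap_extend: float = -1.0
                    ) -> Alignment:
    """Progressive multiple alignment: 3-mer distance -> UPGMA guide tree ->
    profile–profile global alignment along the guide tree."""
    if len(records) < 2:
        raise ValueError("progressive_msa needs >= 2 records")
    sub = blosum62()
    submat = np.array([[sub.get((x, y), sub.get((y, x), -1.0))
                        for y in _AA] for x in _AA])
    labels = [r.id for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(records[i].residues,
                                               records[j].residues)
    guide = upgma(DistanceMatrix(labels, d))
    by_label = {r.id: r for r in records}

    def build(node: Node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.label], [by_label[node.label].residues.upper()]
        parts = [build(c) for c in node.children]
        ids, rows = parts[0]
        for nids, nrows in parts[1:]:
            rows, nrows = _profile_align(rows, nrows, submat,
                                         gap_open, gap_extend)
            ids = ids + nids
            rows = rows + nrows
        return ids, rows

    ids, rows = build(guide.root)
    recs = [SequenceRecord(i, row, "protein", by_label[i].description)
            for i, row in zip(ids, rows)]
    return Alignment(recs)


# ---------------------------------------------------------------------------
# Distances

def pdistance(alignment: Alignment, kimura: bool = False) -> DistanceMatrix:
    """Pairwise mismatch proportion with pairwise gap deletion; optional
    Kimura correction for proteins: d = -ln(1 - p - p^2/5)."""
    rows = [r.residues.upper() for r in alignment.records]
    labels = [r.id for r in alignment.records]
    enc = np.array([[ord(c) for c in row] for row in rows])
    gap = enc == ord("-")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and "
                    f"{labels[j]!r}")
            p = float((enc[i, ok] != enc[j, ok]).sum()) / total
            if kimura:
                arg = 1.0 - p - 0.2 * p * p
                if arg <= 0:
                    raise ValueError("p-distance too large for Kimura correction")
                p = -math.log(arg)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# UPGMA (guide trees, ultrametric check)

def upgma(D: DistanceMatrix) -> Tree:
    """Average-linkage agglomerative tree; deterministic label-pair tie-break."""
    nodes: dict[str, Node] = {lab: Node(label=lab) for lab in D.labels}
    heights = {lab: 0.0 for lab in D.labels}
    sizes = {lab: 1 for lab in D.labels}
    # cluster key = smallest member label
    dist = {(a, b): D[a, b] for a in D.labels for b in D.labels if a < b}
    active = sorted(D.labels)
    while len(active) > 1:
        (a, b) = min(((x, y) for x in active for y in active if x < y),
                     key=lambda p: (dist[p], p))
        h = dist[(a, b)] / 2
        na, nb = nodes[a], nodes[b]
        na.length = h - heights[a]
        nb.length = h - heights[b]
        new = Node(children=[na, nb])
        key = min(a, b)
        other = max(a, b)
        for x in active:
            if x in (a, b):
                continue
            pa = (min(x, a), max(x, a))
            pb = (min(x, b), max(x, b))
            merged = (sizes[a] * dist[pa] + sizes[b] * dist[pb]) / (
                sizes[a] + sizes[b])
            dist[(min(x, key), max(x, key))] = merged
        active.remove(other)
        nodes[key] = new
        heights[key] = h
        sizes[key] = sizes[a] + sizes[b]
    return Tree(nodes[active[0]])


# ---------------------------------------------------------------------------
# Neighbor joining

def nj(D: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining (see module docstring for determinism and
    the negative-branch-length policy)."""
    if len(D.labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    # cluster key = smallest leaf label beneath the node
    nodes: dict[str, Node] = {lab: Node(label=lab) for lab in D.labels}
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(D.labels):
        for j, b in enumerate(D.labels):
            if i < j:
                dist[frozenset((a, b))] = float(D.values[i, j])
    active = sorted(D.labels)

    while len(active) > 3:
        n = len(active)
        r = {x: sum(dist[frozenset((x, y))] for y in active if y != x)
             for x in active}
        best_pair = None
        best_q = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = active[ii], active[jj]
                q = (n - 2) * dist[frozenset((a, b))] - r[a] - r[b]
                key = (q, (a, b))
                if best_q is None or key < best_q:
                    best_q = key
                    best_pair = (a, b)
        a, b = best_pair
        dab = dist[frozenset((a, b))]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        # clamp negatives, transfer the deficit to the sibling branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        na, nb = nodes[a], nodes[b]
        na.length = la
        nb.length = lb
        new = Node(children=[na, nb])
        key = min(a, b)
        for x in active:
            if x in (a, b):
                continue
            dx = 0.5 * (dist[frozenset((x, a))] + dist[frozenset((x, b))] - dab)
            dist[frozenset((x, key))] = max(dx, 0.0)
        active.remove(max(a, b))
        nodes[key] = new

    # trifurcating root from the closed-form three-point formulas
    a, b, c = active
    dab = dist[frozenset((a, b))]
    dac = dist[frozenset((a, c))]
    dbc = dist[frozenset((b, c))]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for lab, length in ((a, la), (b, lb), (c, lc)):
        nodes[lab].length = max(length, 0.0)
    return Tree(Node(children=[nodes[a], nodes[b], nodes[c]]))


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap(alignment: Alignment, n: int = 1000, seed: int = 0,
              distance_kwargs: dict | None = None) -> Tree:
    """NJ tree from the full alignment, with internal-node supports from `n`
    column-resampled replicates (percentage of replicates containing each
    bipartition of the full-data tree)."""
    if n < 1:
        raise ValueError("need at least one bootstrap replicate")
    kwargs = distance_kwargs or {}
    tree = nj(pdistance(alignment, **kwargs))
    target = {}
    sets = tree._leafsets()
    all_leaves = sets[id(tree.root)]
    for node in tree.postorder():
        if node is tree.root or node.is_leaf:
            continue
        side = sets[id(node)]
        target[id(node)] = frozenset([side, all_leaves - side])

    counts = {k: 0 for k in set(target.values())}
    rng = np.random.default_rng(seed)
    n_col = alignment.n_columns
    for _ in range(n):
        cols = rng.integers(0, n_col, size=n_col)
        try:
            rep = nj(pdistance(alignment.column_subset(cols)))
        except ValueError:
            # a replicate with no comparable columns for some pair carries no
            # bipartition information
            continue
        reps = rep.bipartitions()
        for bip in counts:
            if bip in reps:
                counts[bip] += 1

    for node in tree.postorder():
        if id(node) in target:
            node.support = round(100.0 * counts[target[id(node)]] / n)
    return tree
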