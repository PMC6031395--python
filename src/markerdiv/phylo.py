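"""Distances, neighbor joining, phylogenetic placement, and diversity on trees.

Trees are ``dendropy.Tree`` objects throughout.  Distances are Poisson-
corrected p-distances under the same 20-state model used by the simulator;
reference and window trees are built with Saitou-Nei neighbor joining (exact
on additive matrices), and query fragments are placed on a fixed reference
tree by maximizing the Felsenstein pruning likelihood over attachment edges,
in the spirit of maximum-likelihood placement tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from . import _model
from ._model import GAP, N_STATES
from .profile_hmm import AlignedFragment

__all__ = [
    "DistanceMatrix",
    "ReferenceTree",
    "Placement",
    "PDScore",
    "protein_distance",
    "pairwise_distances",
    "neighbor_joining",
    "place_query",
    "assign_group",
    "split_paralogs",
    "total_branch_length",
]

UNCLASSIFIED = "unclassified"
D_MAX = 5.0


class UndefinedDistanceError(ValueError):
    """Raised when two sequences share no mutually ungapped column."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m


def protein_distance(a: str, b: str, d_max: float = D_MAX) -> float:
    """Poisson-corrected distance between two aligned protein sequences.

    p is the mismatch fraction over mutually ungapped columns;
    d = -(19/20) ln(1 - (20/19) p), capped at d_max for saturated pairs.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    n = 0
    mism = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        n += 1
        if x != y:
            mism += 1
    if n == 0:
        raise UndefinedDistanceError("no mutually ungapped columns")
    return _model.poisson_distance(mism / n, d_max=d_max)


def pairwise_distances(
    labels: list[str], seqs: list[str], d_max: float = D_MAX
) -> tuple[DistanceMatrix, list[tuple[str, str]]]:
    """All-pairs Poisson-corrected distances, vectorized.

    Pairs with no shared ungapped columns are imputed with the maximum
    observed distance (or d_max if none is defined) and reported in the
    second return value so callers can flag them.
    """
    n = len(seqs)
    width = len(seqs[0])
    enc = np.empty((n, width), dtype=np.int16)
    for i, s in enumerate(seqs):
        enc[i] = np.frombuffer(s.encode(), dtype=np.uint8)
    resident = enc != ord(GAP)
    dist = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    mism = np.zeros((n, n), dtype=np.int64)
    chunk = max(1, 2_000_000 // max(1, n * width))
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        both = resident[lo:hi, None, :] & resident[None, :, :]
        ne = (enc[lo:hi, None, :] != enc[None, :, :]) & both
        shared[lo:hi] = both.sum(axis=2)
        mism[lo:hi] = ne.sum(axis=2)
    undefined = []
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(shared > 0, mism / np.maximum(shared, 1), np.nan)
    p_cap = _model.expected_p_distance(d_max)
    dist = np.where(p >= p_cap, d_max, -(19.0 / 20.0) * np.log1p(-(20.0 / 19.0) * np.minimum(p, p_cap - 1e-12)))
    np.fill_diagonal(dist, 0.0)
    bad = shared == 0
    np.fill_diagonal(bad, False)
    if bad.any():
        finite = dist[~np.isnan(dist)]
        fill = float(finite.max()) if finite.size else d_max
        for i, j in zip(*np.nonzero(bad)):
            if i < j:
                undefined.append((labels[i], labels[j]))
            dist[i, j] = fill
    return DistanceMatrix(labels=list(labels), matrix=dist), undefined


# ---------------------------------------------------------------------------
# neighbor joining


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch length to 0, moving the deficit to its sibling."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic label-order tie-breaks.

    Negative branch lengths are clamped to zero with the length transferred
    to the sibling branch.  Two-taxon input yields a single edge of length d
    (split evenly across the root).
    """
    labels = list(dm.labels)
    n = len(labels)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    if n < 2:
        raise ValueError("at least 2 taxa are required")
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=lab)
        nodes.append(node)
    if n == 2:
        d = dm.matrix[0, 1]
        for node in nodes:
            tree.seed_node.add_child(node)
            node.edge.length = d / 2.0
        return tree

    d = dm.matrix.copy()
    # sort key per cluster for deterministic tie-breaking
    keys = list(labels)
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = [
            (min(keys[active[a]], keys[active[b]]), max(keys[active[a]], keys[active[b]]), a, b)
            for a, b in zip(*np.nonzero(np.isclose(q, qmin, rtol=0, atol=1e-12)))
            if a < b
        ]
        cand.sort()
        _, _, ai, bi = cand[0]
        i, j = active[ai], active[bi]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = dendropy.Node()
        new.add_child(nodes[i])
        nodes[i].edge.length = li
        new.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances to the new cluster
        dnew = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            dnew[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(dnew) - 1] = dnew[:-1]
        d[: len(dnew) - 1, -1] = dnew[:-1]
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # resolve the final three clusters on the root
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = tree.seed_node
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    return tree


def total_branch_length(tree: dendropy.Tree) -> float:
    """Phylogenetic diversity: the sum of all branch lengths in the tree."""
    return float(
        sum(e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None)
    )


# ---------------------------------------------------------------------------
# reference trees and placement


class ReferenceTree:
    """A rooted reference tree with group-painted edges.

    Edges are identified by a stable preorder index of their head node.  An
    edge is painted with group G iff every leaf below it belongs to G;
    otherwise it is painted ``unclassified`` (strict monophyletic painting).
    """

    def __init__(self, tree: dendropy.Tree, leaf_groups: dict[str, str]):
        self.tree = tree
        self.leaf_groups = dict(leaf_groups)
        self._nodes = list(tree.preorder_node_iter())
        self._edge_id = {id(nd): i for i, nd in enumerate(self._nodes)}
        self._depth = {}
        for nd in self._nodes:
            if nd.edge.length is not None and nd.edge.length < 0:
                raise ValueError("branch lengths must be non-negative")
            p = nd.parent_node
            self._depth[id(nd)] = 0 if p is None else self._depth[id(p)] + 1
        self._labels: dict[int, str] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label not in self.leaf_groups:
                    raise ValueError("every leaf must carry a group label")
                self._labels[id(nd)] = self.leaf_groups[nd.taxon.label]
            else:
                kids = {self._labels[id(c)] for c in nd.child_nodes()}
                self._labels[id(nd)] = kids.pop() if len(kids) == 1 else UNCLASSIFIED

    @property
    def nodes(self):
        return self._nodes

    def edge_id(self, node) -> int:
        return self._edge_id[id(node)]

    def node_of_edge(self, edge_id: int):
        return self._nodes[edge_id]

    def edge_depth(self, edge_id: int) -> int:
        return self._depth[id(self._nodes[edge_id])]

    def edge_group(self, edge_id: int) -> str:
        return self._labels[id(self._nodes[edge_id])]

    def leaf_edge_id(self, label: str) -> int:
        for nd in self._nodes:
            if nd.is_leaf() and nd.taxon.label == label:
                return self.edge_id(nd)
        raise KeyError(label)

    def subtree_edge_ids(self, node) -> set[int]:
        """Edge ids of the node's subtree, including its own subtending edge."""
        out = set()
        stack = [node]
        while stack:
            nd = stack.pop()
            out.add(self.edge_id(nd))
            stack.extend(nd.child_nodes())
        return out

    def mrca(self, labels: set[str]):
        sets = {}
        best = None
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                sets[id(nd)] = {nd.taxon.label}
            else:
                s = set()
                for c in nd.child_nodes():
                    s |= sets[id(c)]
                sets[id(nd)] = s
            if best is None and labels <= sets[id(nd)]:
                best = nd
        return best


@dataclass(frozen=True)
class Placement:
    fragment_id: str
    edge: int
    pendant_length: float
    log_likelihood: float
    assigned_group: str


@dataclass(frozen=True)
class PDScore:
    group: str
    window_start: int
    n_subsampled: int
    pd: float


class UnplaceableError(ValueError):
    """Raised when a query has no usable alignment columns."""


def _leaf_partials(seq: str, cols: np.ndarray) -> np.ndarray:
    """Indicator partial likelihoods (n_sites, 20); gaps are missing data."""
    out = np.zeros((cols.size, N_STATES))
    for s, c in enumerate(cols):
        ch = seq[c]
        if ch == GAP:
            out[s] = 1.0
        else:
            out[s, _model.AA_INDEX[ch]] = 1.0
    return out


def _rescale(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = v.max(axis=1, keepdims=True)
    m = np.where(m > 0, m, 1.0)
    return v / m, np.log(m[:, 0])


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_max(f, lo: float, hi: float, tol: float = 1e-4) -> tuple[float, float]:
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    x = (a + b) / 2.0
    return x, f(x)


def place_query(
    ref: ReferenceTree,
    ref_alignment: dict[str, str],
    query: AlignedFragment,
    pendant_max: float = 5.0,
    tol: float = 1e-4,
) -> Placement:
    """Maximum-likelihood placement of an aligned fragment on the reference tree.

    For every edge the query is attached at the edge midpoint with a pendant
    branch optimized by golden-section search on [0, pendant_max]; the tree
    likelihood is Felsenstein pruning under the 20-state Poisson model
    restricted to the query's ungapped columns.  Ties are broken toward the
    root, then by edge id.
    """
    pairs = [(c, r) for c, r in zip(query.column_map, query.residues) if c is not None]
    if not pairs:
        raise UnplaceableError(f"query {query.fragment_id} has no usable columns")
    cols = np.array([c for c, _ in pairs])
    qres = np.array([_model.AA_INDEX[r] for _, r in pairs])
    n_sites = cols.size

    tree = ref.tree
    down: dict[int, np.ndarray] = {}
    dscale: dict[int, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            seq = ref_alignment[nd.taxon.label]
            v = _leaf_partials(seq, cols)
            sc = np.zeros(n_sites)
        else:
            v = np.ones((n_sites, N_STATES))
            sc = np.zeros(n_sites)
            for c in nd.child_nodes():
                v = v * _model.propagate(down[id(c)], c.edge.length or 0.0)
                sc = sc + dscale[id(c)]
            v, extra = _rescale(v)
            sc = sc + extra
        down[id(nd)] = v
        dscale[id(nd)] = sc

    # "out" partial at the parent end of each node's edge: everything except
    # the node's own subtree.
    out: dict[int, np.ndarray] = {}
    oscale: dict[int, np.ndarray] = {}
    root = tree.seed_node
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        p = nd.parent_node
        if p is root:
            v = np.ones((n_sites, N_STATES))
            sc = np.zeros(n_sites)
        else:
            v = _model.propagate(out[id(p)], p.edge.length or 0.0)
            sc = oscale[id(p)].copy()
        for sib in p.child_nodes():
            if sib is nd:
                continue
            v = v * _model.propagate(down[id(sib)], sib.edge.length or 0.0)
            sc = sc + dscale[id(sib)]
        v, extra = _rescale(v)
        out[id(nd)] = v
        oscale[id(nd)] = sc + extra

    best: tuple[float, int, int, float] | None = None  # (-logL, depth, edge_id, pendant)
    candidates = []
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        t = nd.edge.length or 0.0
        half = t / 2.0
        eb = _model.propagate(down[id(nd)], half) * _model.propagate(out[id(nd)], half)
        scale = dscale[id(nd)] + oscale[id(nd)]
        eb_sum = eb.sum(axis=1)
        eb_q = eb[np.arange(n_sites), qres]
        const = float(scale.sum()) - n_sites * math.log(N_STATES)

        def loglik(lam, eb_sum=eb_sum, eb_q=eb_q, const=const):
            e = math.exp(-_model.BETA * lam)
            vals = (1.0 - e) / N_STATES * eb_sum + e * eb_q
            return float(np.log(np.maximum(vals, 1e-300)).sum()) + const

        lam, ll = _golden_max(loglik, 0.0, pendant_max, tol)
        ll0 = loglik(0.0)
        if ll0 >= ll:
            lam, ll = 0.0, ll0
        eid = ref.edge_id(nd)
        candidates.append((ll, ref.edge_depth(eid), eid, lam))

    best_ll = max(c[0] for c in candidates)
    near = [c for c in candidates if c[0] >= best_ll - 1e-9]
    near.sort(key=lambda c: (c[1], c[2]))
    ll, _, eid, lam = near[0]
    return Placement(
        fragment_id=query.fragment_id,
        edge=eid,
        pendant_length=float(lam),
        log_likelihood=float(ll),
        assigned_group=ref.edge_group(eid),
    )


def assign_group(ref: ReferenceTree, placement: Placement) -> str:
    """Taxonomic label of the placement edge under monophyletic painting."""
    return ref.edge_group(placement.edge)


def split_paralogs(
    placements: list[Placement],
    ref: ReferenceTree,
    clade_a_leaves: set[str],
    clade_b_leaves: set[str],
) -> dict[str, str]:
    """Classify placements into two paralog clades of one group.

    Fragments placed on an edge inside clade A (including its subtending
    edge) map to "A", inside clade B to "B"; anything else is "unassigned".
    """
    node_a = ref.mrca(set(clade_a_leaves))
    node_b = ref.mrca(set(clade_b_leaves))
    edges_a = ref.subtree_edge_ids(node_a)
    edges_b = ref.subtree_edge_ids(node_b)
    if edges_a & edges_b:
        raise ValueError("paralog clades must be disjoint subtrees")
    out = {}
    for pl in placements:
        if pl.edge in edges_a:
            out[pl.fragment_id] = "A"
        elif pl.edge in edges_b:
            out[pl.fragment_id] = "B"
        else:
            out[pl.fragment_id] = "unassigned"
    return out
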