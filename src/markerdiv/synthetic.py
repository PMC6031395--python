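"""Synthetic marker-gene communities with known ground truth.

Real marker-gene surveys of this kind start from curated reference databases
and hundreds of millions of metagenomic ORFs; none of that is required to
exercise the analysis machinery.  This module builds clade-structured
reference families (one Yule radiation per taxonomic group hung off a shared
root), evolves gapless reference alignments under the 20-state Poisson model,
draws metagenome-like protein fragments from hidden "strains" of known
lineages, grafts an ancient gene-duplication scenario onto one group, and
simulates codon-sequence pairs under a specified Ka/Ks ratio.  Every output
carries its generating truth so downstream stages can be scored.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Data import CodonTable
from scipy.linalg import expm

from . import _model
from ._model import N_STATES

__all__ = [
    "GroupSpec",
    "CommunityConfig",
    "Fragment",
    "FragmentTruth",
    "ParalogMap",
    "SimulatedCommunity",
    "CodonPairSpec",
    "simulate_tree",
    "evolve_protein",
    "make_community",
    "make_paralog_scenario",
    "simulate_codon_pair",
]


@dataclass(frozen=True)
class GroupSpec:
    """One taxonomic group: a radiation of n_lineages reference lineages."""

    name: str
    n_lineages: int
    radiation_depth: float  # expected substitutions/site, root-to-tip of the group
    within_lineage_depth: float  # strain divergence used when drawing fragments

    def __post_init__(self):
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if self.radiation_depth <= 0:
            raise ValueError("radiation_depth must be > 0")
        if self.within_lineage_depth < 0:
            raise ValueError("within_lineage_depth must be >= 0")


@dataclass(frozen=True)
class CommunityConfig:
    """Design of a synthetic marker-gene community.

    ``fragment_min_len`` defaults to 150 residues, the conventional lower
    bound for metagenomic ORFs included in marker screens.  ``stem_depth`` is
    the branch joining each group's radiation to the shared root, i.e. the
    between-group divergence.
    """

    groups: tuple[GroupSpec, ...]
    fragment_count: int
    fragment_min_len: int = 150
    fragment_max_len: int | None = None
    alignment_len: int = 400
    stem_depth: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(
            g if isinstance(g, GroupSpec) else GroupSpec(*g) for g in self.groups
        ))
        if not self.groups:
            raise ValueError("at least one group is required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        if self.fragment_count < 0:
            raise ValueError("fragment_count must be >= 0")
        if self.fragment_min_len < 1:
            raise ValueError("fragment_min_len must be >= 1")
        if self.alignment_len < self.fragment_min_len:
            raise ValueError("alignment_len must be >= fragment_min_len")
        if self.fragment_max_len is not None:
            if not (self.fragment_min_len <= self.fragment_max_len <= self.alignment_len):
                raise ValueError("fragment_max_len must lie in [fragment_min_len, alignment_len]")


@dataclass(frozen=True)
class Fragment:
    id: str
    seq: str


@dataclass(frozen=True)
class FragmentTruth:
    """Hidden generating coordinates of a fragment (0-based half-open columns)."""

    group: str
    lineage: str  # reference leaf label the strain was drawn from
    start_col: int
    length: int
    paralog: str | None = None  # "A"/"B" in duplication scenarios


@dataclass(frozen=True)
class ParalogMap:
    """Truth record for an ancient-duplication scenario in one group."""

    group: str
    dup_lineages: tuple[str, ...]
    clade_a_leaves: tuple[str, ...]
    clade_b_leaves: tuple[str, ...]


@dataclass
class SimulatedCommunity:
    config: CommunityConfig
    reference_ids: list[str]
    reference_seqs: dict[str, str]  # gapless, all alignment_len long
    reference_groups: dict[str, str]
    reference_tree: dendropy.Tree
    fragments: list[Fragment]
    truth: dict[str, FragmentTruth]
    paralog_map: ParalogMap | None = None
    # internal node sequences of the reference tree, keyed by node id; kept so
    # duplication scenarios can branch off ancestral sequences.
    node_seqs: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def alignment_len(self) -> int:
        return self.config.alignment_len

    def group_alignment(self, group: str) -> dict[str, str]:
        return {r: self.reference_seqs[r] for r in self.reference_ids
                if self.reference_groups[r] == group}


@dataclass(frozen=True)
class CodonPairSpec:
    """Specification for one pair of coding sequences diverged under omega."""

    n_codons: int
    omega: float  # Ka/Ks ratio
    t: float  # expected substitutions per codon separating the pair
    kappa: float = 2.0  # transition/transversion rate ratio
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


# ---------------------------------------------------------------------------
# trees


def simulate_tree(
    n_leaves: int,
    depth: float,
    seed: int,
    labels: list[str] | None = None,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Random Yule (pure-birth) tree rescaled to a target mean root-to-tip depth.

    The tree is ultrametric, so after rescaling every root-to-tip path equals
    ``depth`` exactly.  Deterministic for a given seed.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    tns = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    birth: dict[int, float] = {}
    t = 0.0
    c1, c2 = root.new_child(), root.new_child()
    birth[id(c1)] = birth[id(c2)] = 0.0
    active = [c1, c2]
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.edge.length = t - birth[id(node)]
        k1, k2 = node.new_child(), node.new_child()
        birth[id(k1)] = birth[id(k2)] = t
        active.extend([k1, k2])
    total = t + rng.exponential(1.0 / len(active))
    for leaf in active:
        leaf.edge.length = total - birth[id(leaf)]
    scale = depth / total
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    leaves = list(tree.leaf_node_iter())
    if labels is None:
        labels = [f"T{i + 1:03d}" for i in range(len(leaves))]
    if len(labels) != len(leaves):
        raise ValueError("number of labels must equal n_leaves")
    for leaf, lab in zip(leaves, labels):
        leaf.taxon = tns.require_taxon(label=lab)
    return tree


def _evolve_arrays(
    root_states: np.ndarray, tree: dendropy.Tree, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Evolve a state vector over every node of the tree (preorder)."""
    seqs: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = root_states.copy()
        else:
            t = node.edge.length or 0.0
            seqs[id(node)] = _model.evolve_states(seqs[id(node.parent_node)], t, rng)
    return seqs


def evolve_protein(root: str, tree: dendropy.Tree, seed: int) -> dict[str, str]:
    """Evolve a root protein down a tree; returns leaf label -> sequence.

    Indel-free Poisson 20-state model: all leaves keep the root's length.
    """
    if len(root) == 0:
        raise ValueError("root sequence must be non-empty")
    rng = np.random.default_rng(seed)
    states = _model.encode(root)
    if (states < 0).any():
        raise ValueError("root sequence must be gapless")
    seqs = _evolve_arrays(states, tree, rng)
    return {
        leaf.taxon.label: _model.decode(seqs[id(leaf)])
        for leaf in tree.leaf_node_iter()
    }


# ---------------------------------------------------------------------------
# communities


def _draw_fragment(
    ref_states: np.ndarray,
    within_depth: float,
    min_len: int,
    max_len: int,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Evolve a strain from a reference lineage and cut a contiguous region."""
    strain = _model.evolve_states(ref_states, within_depth, rng)
    n = strain.shape[0]
    length = int(rng.integers(min_len, max_len + 1))
    start = int(rng.integers(0, n - length + 1))
    return _model.decode(strain[start:start + length]), start, length


def make_community(config: CommunityConfig) -> SimulatedCommunity:
    """Build reference alignment + tree and draw labelled fragments.

    Per group a Yule radiation of ``n_lineages`` leaves at ``radiation_depth``
    is hung off a shared root by a ``stem_depth`` branch; references are the
    evolved leaf sequences (gapless, already aligned by construction).
    Fragments are assigned round-robin across groups, drawn from a random
    lineage by evolving a strain at ``within_lineage_depth`` and cutting a
    contiguous region of at least ``fragment_min_len`` residues.
    """
    rng = np.random.default_rng(config.seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    root_states = rng.integers(0, N_STATES, size=config.alignment_len, dtype=np.int8)

    node_seqs: dict[int, np.ndarray] = {id(root): root_states.copy()}
    reference_ids: list[str] = []
    reference_seqs: dict[str, str] = {}
    reference_groups: dict[str, str] = {}
    group_leaf_states: dict[str, dict[str, np.ndarray]] = {}

    for group in config.groups:
        anc = _model.evolve_states(root_states, config.stem_depth, rng)
        labels = [f"{group.name}|L{i + 1:03d}" for i in range(group.n_lineages)]
        if group.n_lineages == 1:
            gnode = root.new_child(edge_length=config.stem_depth + group.radiation_depth)
            gnode.taxon = tns.require_taxon(label=labels[0])
            leaf_states = {labels[0]: _model.evolve_states(anc, group.radiation_depth, rng)}
            node_seqs[id(gnode)] = leaf_states[labels[0]]
        else:
            sub = simulate_tree(
                group.n_lineages,
                group.radiation_depth,
                seed=int(rng.integers(2**31)),
                labels=labels,
                taxon_namespace=tns,
            )
            sub_seqs = _evolve_arrays(anc, sub, rng)
            gtop = sub.seed_node
            gtop.edge.length = config.stem_depth
            root.add_child(gtop)
            node_seqs.update(sub_seqs)
            leaf_states = {
                leaf.taxon.label: sub_seqs[id(leaf)] for leaf in gtop.leaf_iter()
            }
        group_leaf_states[group.name] = leaf_states
        for lab in labels:
            reference_ids.append(lab)
            reference_seqs[lab] = _model.decode(leaf_states[lab])
            reference_groups[lab] = group.name

    max_len = config.fragment_max_len or config.alignment_len
    fragments: list[Fragment] = []
    truth: dict[str, FragmentTruth] = {}
    for i in range(config.fragment_count):
        group = config.groups[i % len(config.groups)]
        lineages = sorted(group_leaf_states[group.name])
        lineage = lineages[int(rng.integers(len(lineages)))]
        seq, start, length = _draw_fragment(
            group_leaf_states[group.name][lineage],
            group.within_lineage_depth,
            config.fragment_min_len,
            max_len,
            rng,
        )
        fid = f"frag{i:05d}"
        fragments.append(Fragment(fid, seq))
        truth[fid] = FragmentTruth(group.name, lineage, start, length)

    return SimulatedCommunity(
        config=config,
        reference_ids=reference_ids,
        reference_seqs=reference_seqs,
        reference_groups=reference_groups,
        reference_tree=tree,
        fragments=fragments,
        truth=truth,
        node_seqs=node_seqs,
    )


def _leaf_label_sets(tree: dendropy.Tree) -> dict[int, frozenset[str]]:
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset({node.taxon.label})
        else:
            s: set[str] = set()
            for c in node.child_nodes():
                s |= sets[id(c)]
            sets[id(node)] = frozenset(s)
    return sets


def _mrca(tree: dendropy.Tree, labels: set[str]):
    """Smallest node whose leaf set contains all the given labels."""
    sets = _leaf_label_sets(tree)
    best = None
    for node in tree.postorder_node_iter():
        if labels <= sets[id(node)]:
            best = node
            break
    if best is None:
        raise ValueError("labels not found in tree")
    return best


def _induced_subtree(node, keep: set[str]):
    """Copy of the subtree rooted at node induced on the leaf labels in keep.

    Returns (new_node, edge_length) or None; unifurcations are suppressed with
    their edge lengths summed.  Leaf labels get a '|B' suffix.
    """
    if node.is_leaf():
        if node.taxon.label in keep:
            new = dendropy.Node()
            new.label = node.taxon.label + "|B"
            return new, (node.edge.length or 0.0)
        return None
    kids = []
    for c in node.child_nodes():
        r = _induced_subtree(c, keep)
        if r is not None:
            kids.append(r)
    if not kids:
        return None
    if len(kids) == 1:
        child, elen = kids[0]
        return child, elen + (node.edge.length or 0.0)
    new = dendropy.Node()
    for child, elen in kids:
        new.add_child(child)
        child.edge.length = elen
    return new, (node.edge.length or 0.0)


def make_paralog_scenario(
    base: SimulatedCommunity,
    n_dup_lineages: int,
    dup_depth: float,
    seed: int,
    group: str | None = None,
) -> SimulatedCommunity:
    """Graft an ancient duplication of the marker onto a community.

    The marker is duplicated in the first ``n_dup_lineages`` lineages of the
    target group (default: the first group): a second 'B' copy branches off
    the lineages' common ancestor and re-radiates along a copy of their
    subtree, after a stem of 2*dup_depth (dup_depth of divergence on each
    side of the duplication).  Fragments drawn from the duplicated lineages
    are doubled, with the new fragments drawn from the B copies; truth labels
    record the paralog clade of every affected fragment.
    """
    if n_dup_lineages == 0:
        return base
    cfg = base.config
    gname = group if group is not None else cfg.groups[0].name
    gspec = next(g for g in cfg.groups if g.name == gname)
    if n_dup_lineages > gspec.n_lineages:
        raise ValueError("n_dup_lineages exceeds the group's lineage count")
    if dup_depth <= 0:
        raise ValueError("dup_depth must be > 0")

    rng = np.random.default_rng(seed)
    dup_lineages = sorted(
        r for r in base.reference_ids if base.reference_groups[r] == gname
    )[:n_dup_lineages]
    dup_set = set(dup_lineages)

    tree = copy.deepcopy(base.reference_tree)
    anc = _mrca(tree, dup_set)
    anc_base = _mrca(base.reference_tree, dup_set)
    anc_states = base.node_seqs[id(anc_base)]

    # restructure: anc's children move under a zero-length 'A' node; the B
    # clade (stem 2*dup_depth, then a copy of the induced subtree) is its
    # sister.  Clades A and B are then disjoint subtrees.
    a_node = dendropy.Node()
    a_node.edge.length = 0.0
    for c in list(anc.child_nodes()):
        anc.remove_child(c)
        a_node.add_child(c)
    b_node, _ = _induced_subtree(anc_base, dup_set)
    b_node.edge.length = 2.0 * dup_depth
    anc.add_child(a_node)
    anc.add_child(b_node)

    # evolve B-copy reference sequences down the B clade
    b_seqs: dict[int, np.ndarray] = {}
    b_seqs[id(b_node)] = _model.evolve_states(anc_states, 2.0 * dup_depth, rng)
    b_leaf_states: dict[str, np.ndarray] = {}
    stack = [b_node]
    while stack:
        node = stack.pop()
        if node is not b_node:
            b_seqs[id(node)] = _model.evolve_states(
                b_seqs[id(node.parent_node)], node.edge.length or 0.0, rng
            )
        if node.num_child_nodes() == 0:
            b_leaf_states[node.label] = b_seqs[id(node)]
            node.taxon = tree.taxon_namespace.require_taxon(label=node.label)
            node.label = None
        else:
            stack.extend(reversed(node.child_nodes()))

    reference_ids = list(base.reference_ids)
    reference_seqs = dict(base.reference_seqs)
    reference_groups = dict(base.reference_groups)
    for lab in sorted(b_leaf_states):
        reference_ids.append(lab)
        reference_seqs[lab] = _model.decode(b_leaf_states[lab])
        reference_groups[lab] = gname

    sets = _leaf_label_sets(tree)
    paralog_map = ParalogMap(
        group=gname,
        dup_lineages=tuple(dup_lineages),
        clade_a_leaves=tuple(sorted(sets[id(a_node)])),
        clade_b_leaves=tuple(sorted(sets[id(b_node)])),
    )

    max_len = cfg.fragment_max_len or cfg.alignment_len
    fragments = list(base.fragments)
    truth = dict(base.truth)
    for frag in base.fragments:
        ft = base.truth[frag.id]
        if ft.lineage in dup_set:
            truth[frag.id] = dataclasses.replace(ft, paralog="A")
            b_lineage = ft.lineage + "|B"
            seq, start, length = _draw_fragment(
                b_leaf_states[b_lineage],
                gspec.within_lineage_depth,
                cfg.fragment_min_len,
                max_len,
                rng,
            )
            fid = frag.id + "|B"
            fragments.append(Fragment(fid, seq))
            truth[fid] = FragmentTruth(gname, b_lineage, start, length, paralog="B")

    return SimulatedCommunity(
        config=cfg,
        reference_ids=reference_ids,
        reference_seqs=reference_seqs,
        reference_groups=reference_groups,
        reference_tree=tree,
        fragments=fragments,
        truth=truth,
        paralog_map=paralog_map,
        node_seqs={},
    )


# ---------------------------------------------------------------------------
# codon pairs

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_CODON_TABLE.forward_table))
STOP_CODONS: frozenset[str] = frozenset(_CODON_TABLE.stop_codons)
CODON_AA: dict[str, str] = dict(_CODON_TABLE.forward_table)

_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _gy94_rate_matrix(omega: float, kappa: float) -> np.ndarray:
    """Rate matrix over the 61 sense codons, uniform codon frequencies.

    Single-nucleotide changes only; rate kappa for transitions, multiplied by
    omega for non-synonymous changes; zero to/from stop codons.  Scaled so the
    mean substitution rate is 1 (branch lengths = expected subs per codon).
    """
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            rate = kappa if _is_transition(a, b) else 1.0
            if CODON_AA[ci] != CODON_AA[cj]:
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -np.mean(np.diag(q))
    if mu > 0:
        q /= mu
    return q


def simulate_codon_pair(spec: CodonPairSpec) -> tuple[str, str]:
    """Two coding sequences diverged from a common ancestor under GY94.

    The ancestor is uniform over sense codons; each descendant evolves
    independently for t/2 expected substitutions per codon.  Codon sites are
    independent; the kernel is the exact matrix exponential, so the contract
    is distributional.  No stop codons are ever emitted.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(SENSE_CODONS)
    anc = rng.integers(0, n, size=spec.n_codons)
    if spec.t == 0:
        seq = "".join(SENSE_CODONS[i] for i in anc)
        return seq, seq
    q = _gy94_rate_matrix(spec.omega, spec.kappa)
    p = expm(q * (spec.t / 2.0))
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    out = []
    for _ in range(2):
        u = rng.random(spec.n_codons)
        idx = np.empty(spec.n_codons, dtype=np.int64)
        for k in range(spec.n_codons):
            idx[k] = np.searchsorted(cum[anc[k]], u[k], side="right")
        idx = np.minimum(idx, n - 1)
        out.append("".join(SENSE_CODONS[i] for i in idx))
    return out[0], out[1]
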