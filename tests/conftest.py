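import numpy as np
import pytest

from markerdiv import phylo, pipeline
from markerdiv import synthetic as syn
from markerdiv.profile_hmm import AlignedFragment


@pytest.fixture(scope="session")
def community():
    """Small three-group community shared by placement/profile tests."""
    cfg = syn.CommunityConfig(
        groups=(
            syn.GroupSpec("V", 8, 1.5, 0.05),
            syn.GroupSpec("B", 5, 0.8, 0.05),
            syn.GroupSpec("A", 5, 0.8, 0.05),
        ),
        fragment_count=90,
        alignment_len=300,
        seed=11,
    )
    return syn.make_community(cfg)


@pytest.fixture(scope="session")
def profiles(community):
    return pipeline.build_group_profiles(community, n_null=200, seed=3)


@pytest.fixture(scope="session")
def reference(community):
    return phylo.ReferenceTree(community.reference_tree, community.reference_groups)


def truth_aligned(com, frag):
    """AlignedFragment built from a fragment's hidden generating coordinates."""
    t = com.truth[frag.id]
    cols = tuple(range(t.start_col, t.start_col + t.length))
    return AlignedFragment(
        fragment_id=frag.id,
        group=t.group,
        residues=frag.seq,
        column_map=cols,
        span=(t.start_col, t.start_col + t.length - 1),
    )


def bipartitions(tree):
    """Non-trivial unrooted bipartitions as frozensets of leaf labels."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        if 1 < len(below) < len(all_leaves) - 1:
            side = min(below, all_leaves - below, key=sorted)
            out.add(side)
    return out


def random_additive_case(n_taxa, seed):
    """A random tree plus the exact patristic distance matrix it induces."""
    tree = syn.simulate_tree(n_taxa, 1.0, seed=seed)
    rng = np.random.default_rng(seed + 10_000)
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    mat = np.array([[pdm.patristic_distance(a, b) for b in taxa] for a in taxa])
    return tree, phylo.DistanceMatrix(labels, mat)
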