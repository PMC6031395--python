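"""Distances, NJ exactness, placement, painting, paralog splitting, PD."""

import dendropy
import numpy as np
import pytest

from markerdiv import _model, phylo
from markerdiv.profile_hmm import AlignedFragment
from conftest import bipartitions, random_additive_case, truth_aligned


class TestProteinDistance:
    def test_identical_sequences_distance_zero(self):
        assert phylo.protein_distance("ACDEF", "ACDEF") == 0.0

    def test_formula_at_p_ten_percent(self):
        # p = 0.1 -> d = -(19/20) ln(1 - (20/19) 0.1)
        a = "A" * 10
        b = "C" + "A" * 9
        expected = -(19 / 20) * np.log(1 - (20 / 19) * 0.1)
        assert phylo.protein_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.10566, abs=1e-4)

    def test_saturated_pair_returns_cap_exactly(self):
        a = "ACDEFGHIKLMNPQRSTVWY"
        b = "CDEFGHIKLMNPQRSTVWYA"  # all 20 sites differ
        assert phylo.protein_distance(a, b) == 5.0

    def test_no_shared_columns_is_an_error(self):
        with pytest.raises(phylo.UndefinedDistanceError):
            phylo.protein_distance("AC--", "--DE")

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        seqs = []
        for _ in range(6):
            chars = rng.choice(list(_model.AMINO_ACIDS), 50)
            gaps = rng.random(50) < 0.1
            seqs.append("".join("-" if g else c for c, g in zip(chars, gaps)))
        labels = [f"s{i}" for i in range(6)]
        dm, _ = phylo.pairwise_distances(labels, seqs)
        for i in range(6):
            for j in range(i + 1, 6):
                assert dm.matrix[i, j] == pytest.approx(
                    phylo.protein_distance(seqs[i], seqs[j]), abs=1e-12
                )


class TestNeighborJoining:
    def test_hand_additive_case(self):
        # generating tree ((A:1,B:2):1,(C:3,D:4):0) -> distances by hand
        dm = phylo.DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float),
        )
        tree = phylo.neighbor_joining(dm)
        assert phylo.total_branch_length(tree) == pytest.approx(11.0, abs=1e-9)
        assert bipartitions(tree) == {frozenset({"A", "B"})}

    def test_three_taxa_closed_form(self):
        dm = phylo.DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        )
        tree = phylo.neighbor_joining(dm)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_two_taxa_single_edge(self):
        dm = phylo.DistanceMatrix(["A", "B"], np.array([[0, 0.7], [0.7, 0]]))
        tree = phylo.neighbor_joining(dm)
        assert phylo.total_branch_length(tree) == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_on_random_additive_matrices(self, seed):
        n = 6 + seed % 5
        gen, dm = random_additive_case(n, seed)
        nj = phylo.neighbor_joining(dm)
        assert bipartitions(nj) == bipartitions(gen)
        assert phylo.total_branch_length(nj) == pytest.approx(
            phylo.total_branch_length(gen), abs=1e-9
        )

    def test_label_permutation_gives_same_topology(self):
        gen, dm = random_additive_case(8, 123)
        perm = [3, 1, 7, 0, 5, 2, 6, 4]
        dm2 = phylo.DistanceMatrix(
            [dm.labels[i] for i in perm], dm.matrix[np.ix_(perm, perm)]
        )
        assert bipartitions(phylo.neighbor_joining(dm)) == bipartitions(
            phylo.neighbor_joining(dm2)
        )

    def test_agrees_with_skbio_on_noisy_matrix(self):
        # independent implementation cross-check on a generic (tie-free)
        # non-additive matrix: same unrooted topology, same total length
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix as SkDM

        rng = np.random.default_rng(7)
        gen, dm = random_additive_case(8, 77)
        noise = rng.uniform(0, 0.05, dm.matrix.shape)
        noisy = dm.matrix + noise + noise.T
        noisy = (noisy + noisy.T) / 2.0
        np.fill_diagonal(noisy, 0.0)
        ours = phylo.neighbor_joining(phylo.DistanceMatrix(dm.labels, noisy))
        theirs = skbio_tree.nj(SkDM(noisy, ids=dm.labels))
        theirs_dp = dendropy.Tree.get(data=str(theirs), schema="newick")
        assert bipartitions(ours) == bipartitions(theirs_dp)


class TestTotalBranchLength:
    def test_three_leaf_star(self):
        tree = dendropy.Tree.get(data="(A:1.0,B:1.0,C:1.0);", schema="newick")
        assert phylo.total_branch_length(tree) == pytest.approx(3.0)

    def test_single_edge(self):
        tree = dendropy.Tree.get(data="(A:0.7);", schema="newick")
        assert phylo.total_branch_length(tree) == pytest.approx(0.7)

    def test_pd_monotone_under_leaf_addition(self):
        tree = dendropy.Tree.get(data="((A:1,B:2):1,C:3);", schema="newick")
        before = phylo.total_branch_length(tree)
        leaf_a = [l for l in tree.leaf_node_iter() if l.taxon.label == "A"][0]
        new = leaf_a.parent_node.new_child(edge_length=0.4)
        new.taxon = tree.taxon_namespace.require_taxon("D")
        assert phylo.total_branch_length(tree) >= before


def _naive_attach_loglik(ref, ref_alignment, query, edge_id, pendant):
    """Independent likelihood oracle: graft the query into a copied tree and
    run plain postorder pruning over the query's columns."""
    import copy

    pairs = [(c, r) for c, r in zip(query.column_map, query.residues) if c is not None]
    cols = np.array([c for c, _ in pairs])
    tree = copy.deepcopy(ref.tree)
    nodes = list(tree.preorder_node_iter())
    target = nodes[edge_id]
    t = target.edge.length or 0.0
    parent = target.parent_node
    mid = dendropy.Node()
    parent.remove_child(target)
    parent.add_child(mid)
    mid.edge.length = t / 2.0
    mid.add_child(target)
    target.edge.length = t / 2.0
    q = mid.new_child(edge_length=pendant)
    q.taxon = tree.taxon_namespace.require_taxon("__query__")
    seqs = dict(ref_alignment)
    qrow = ["-"] * (max(cols) + 1)
    for c, r in pairs:
        qrow[c] = r
    seqs["__query__"] = "".join(qrow)

    partials = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            partials[id(nd)] = phylo._leaf_partials(seqs[nd.taxon.label], cols)
        else:
            v = np.ones((cols.size, 20))
            for c in nd.child_nodes():
                v = v * _model.propagate(partials[id(c)], c.edge.length or 0.0)
            partials[id(nd)] = v
    root_p = partials[id(tree.seed_node)]
    return float(np.log(root_p.sum(axis=1) / 20.0).sum())


class TestPlacement:
    def test_query_identical_to_leaf_places_on_its_pendant_edge(
        self, reference, community
    ):
        rid = community.reference_ids[0]
        frag = AlignedFragment(
            "q", "V", community.reference_seqs[rid][40:240],
            tuple(range(40, 240)), (40, 239),
        )
        pl = phylo.place_query(reference, community.reference_seqs, frag)
        assert pl.edge == reference.leaf_edge_id(rid)
        assert pl.pendant_length <= 1e-3

    def test_loglik_matches_naive_pruning_oracle(self, reference, community):
        frag = truth_aligned(community, community.fragments[0])
        pl = phylo.place_query(reference, community.reference_seqs, frag)
        naive = _naive_attach_loglik(
            reference, community.reference_seqs, frag, pl.edge, pl.pendant_length
        )
        assert pl.log_likelihood == pytest.approx(naive, abs=1e-6)

    def test_best_edge_beats_other_edges(self, reference, community):
        # argmax contract: spot-check the returned placement against a naive
        # per-edge scan with the same pendant optimization grid
        frag = truth_aligned(community, community.fragments[1])
        pl = phylo.place_query(reference, community.reference_seqs, frag)
        rng = np.random.default_rng(0)
        others = rng.choice(
            [e for e in range(1, len(reference.nodes)) if e != pl.edge], 5, replace=False
        )
        for eid in others:
            best_other = max(
                _naive_attach_loglik(
                    reference, community.reference_seqs, frag, int(eid), lam
                )
                for lam in [0.0, 0.01, 0.05, 0.1, 0.3, 1.0]
            )
            assert pl.log_likelihood >= best_other - 1e-9

    def test_group_assignment_accuracy_at_low_divergence(
        self, reference, community
    ):
        correct = 0
        frags = community.fragments[:60]
        for frag in frags:
            t = community.truth[frag.id]
            pl = phylo.place_query(
                reference, community.reference_seqs, truth_aligned(community, frag)
            )
            correct += pl.assigned_group == t.group
        assert correct / len(frags) >= 0.95

    def test_zero_usable_columns_is_unplaceable(self, reference, community):
        frag = AlignedFragment("q", "V", "ACD", (None, None, None), (0, 0))
        with pytest.raises(phylo.UnplaceableError):
            phylo.place_query(reference, community.reference_seqs, frag)


class TestAssignGroupPainting:
    def test_pendant_edge_carries_leaf_group(self, reference, community):
        rid = community.reference_ids[0]
        eid = reference.leaf_edge_id(rid)
        assert reference.edge_group(eid) == community.reference_groups[rid]

    def test_root_edges_of_mixed_clades_are_unclassified(self, reference):
        assert reference.edge_group(0) == phylo.UNCLASSIFIED

    def test_every_within_group_edge_painted_with_group(self, reference, community):
        for nd in reference.nodes[1:]:
            leaves = {l.taxon.label for l in nd.leaf_iter()}
            groups = {community.reference_groups[l] for l in leaves}
            expected = groups.pop() if len(groups) == 1 else phylo.UNCLASSIFIED
            assert reference.edge_group(reference.edge_id(nd)) == expected


class TestSplitParalogs:
    def _make(self):
        tree = dendropy.Tree.get(
            data="(((a1:1,a2:1):1,(b1:1,b2:1):1):1,(x1:1,x2:1):2);",
            schema="newick",
        )
        groups = {l.taxon.label: ("V" if l.taxon.label[0] in "ab" else "O")
                  for l in tree.leaf_node_iter()}
        return phylo.ReferenceTree(tree, groups)

    def test_membership_and_unassigned(self):
        ref = self._make()
        pa = phylo.Placement("f1", ref.leaf_edge_id("a1"), 0.0, -1.0, "V")
        pb = phylo.Placement("f2", ref.leaf_edge_id("b2"), 0.0, -1.0, "V")
        pr = phylo.Placement("f3", 1, 0.0, -1.0, "V")  # group root edge
        out = phylo.split_paralogs(
            [pa, pb, pr], ref, {"a1", "a2"}, {"b1", "b2"}
        )
        assert out == {"f1": "A", "f2": "B", "f3": "unassigned"}

    def test_overlapping_clades_rejected(self):
        ref = self._make()
        with pytest.raises(ValueError):
            phylo.split_paralogs([], ref, {"a1", "a2"}, {"a2", "b1"})
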