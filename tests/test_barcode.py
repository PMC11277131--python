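"""p-distances, haplogroup clustering, neighbor joining and diagnostic sites."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import karyodelim as kd

SEQ = st.text("ACGT", min_size=1, max_size=40)
SEQ_N = st.text("ACGTN-", min_size=1, max_size=40)


class TestPDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "ACGA", 0.25),
        ("ACGN", "ACGA", 0.0),          # N excluded: 0 mismatches / 3 sites
        ("AC-T", "ACGT", 0.0),          # gap excluded
        ("ACRT", "ACGT", 0.0),          # IUPAC ambiguity excluded
    ])
    def test_hand_enumerated_values(self, a, b, expected):
        assert kd.p_distance(a, b) == pytest.approx(expected)

    def test_zero_comparable_sites_is_undefined_not_zero(self):
        assert math.isnan(kd.p_distance("NNNN", "ACGT"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kd.p_distance("ACGT", "ACG")

    @given(st.integers(1, 40).flatmap(
        lambda n: st.tuples(st.text("ACGTN-", min_size=n, max_size=n),
                            st.text("ACGTN-", min_size=n, max_size=n))))
    def test_symmetric_and_bounded(self, pair):
        a, b = pair
        d = kd.p_distance(a, b)
        assert kd.p_distance(b, a) == d or (math.isnan(d)
                                            and math.isnan(kd.p_distance(b, a)))
        if not math.isnan(d):
            assert 0.0 <= d <= 1.0
            comparable = [(x, y) for x, y in zip(a, b)
                          if x in "ACGT" and y in "ACGT"]
            assert (d == 0.0) == all(x == y for x, y in comparable)


class TestDistanceMatrix:
    def test_entries_match_pairwise_oracle(self, tiny_alignment):
        dm = kd.distance_matrix(tiny_alignment)
        for i, a in enumerate(tiny_alignment.ids):
            for j, b in enumerate(tiny_alignment.ids):
                expected = (0.0 if i == j else kd.p_distance(
                    tiny_alignment.sequences[i], tiny_alignment.sequences[j]))
                assert dm.values[i, j] == pytest.approx(expected)

    def test_symmetry_and_zero_diagonal(self, tiny_alignment):
        dm = kd.distance_matrix(tiny_alignment)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_undefined_pairs_flagged(self):
        aln = kd.Alignment(["a", "b"], ["NNNN", "ACGT"])
        dm = kd.distance_matrix(aln)
        assert dm.has_undefined


class TestClusterHaplogroups:
    def _block_matrix(self):
        ids = ["a1", "a2", "b1", "b2"]
        v = np.full((4, 4), 0.10)
        v[:2, :2] = 0.0
        v[2:, 2:] = 0.0
        return kd.DistanceMatrix(ids, v)

    def test_two_blocks_split_at_small_theta(self):
        hg = kd.cluster_haplogroups(self._block_matrix(), 0.02)
        assert hg["a1"] == hg["a2"] != hg["b1"] == hg["b2"]

    def test_theta_one_merges_everything(self):
        hg = kd.cluster_haplogroups(self._block_matrix(), 1.0)
        assert len(set(hg.assignments.values())) == 1

    def test_identical_samples_one_group(self):
        dm = kd.DistanceMatrix(["x", "y", "z"], np.zeros((3, 3)))
        hg = kd.cluster_haplogroups(dm, 0.02)
        assert set(hg.assignments.values()) == {"H1"}

    def test_partition_invariant_to_input_order(self):
        dm = self._block_matrix()
        perm = [2, 0, 3, 1]
        dm2 = kd.DistanceMatrix([dm.ids[i] for i in perm],
                                dm.values[np.ix_(perm, perm)])
        part1 = frozenset(frozenset(v) for v in
                          kd.cluster_haplogroups(dm, 0.02).groups().values())
        part2 = frozenset(frozenset(v) for v in
                          kd.cluster_haplogroups(dm2, 0.02).groups().values())
        assert part1 == part2

    def test_theta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kd.cluster_haplogroups(self._block_matrix(), 1.5)


def _splits(tree):
    """Non-trivial leaf bipartitions of an unrooted dendropy tree."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset({side, leaves - side}))
    return out


def _ls_fit(topology_splits, ids, d):
    """Least-squares branch-length fit of a 4-taxon topology; returns RSS."""
    pairs = list(itertools.combinations(range(4), 2))
    split = next(iter(topology_splits))
    side = sorted(next(iter(split)))
    # design: 5 edges (4 pendant + 1 internal)
    X = np.zeros((6, 5))
    y = np.array([d[i, j] for i, j in pairs])
    for r, (i, j) in enumerate(pairs):
        X[r, i] = 1
        X[r, j] = 1
        crosses = (ids[i] in side) != (ids[j] in side)
        if crosses:
            X[r, 4] = 1
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(((X @ beta - y) ** 2).sum())


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = kd.neighbor_joining(kd.DistanceMatrix(["A", "B", "C"], d))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["B"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["C"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_recovers_generating_topology_on_additive_matrix(self):
        # tree ((A,B),(C,D)) with pendant lengths 1,2,3,4 and internal 1
        ids = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = kd.neighbor_joining(kd.DistanceMatrix(ids, d))
        got = _splits(tree)
        expected = frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        assert got == {expected}
        # oracle: of the 3 unrooted topologies the generating one fits best
        topologies = [frozenset({frozenset({frozenset({a, b}),
                                            frozenset(set(ids) - {a, b})})})
                      for a, b in [("A", "B"), ("A", "C"), ("A", "D")]]
        fits = [_ls_fit(t, ids, d) for t in topologies]
        assert fits.index(min(fits)) == 0

    def test_ultrametric_pairs_become_cherries(self):
        ids = ["A", "B", "C", "D"]
        v = np.full((4, 4), 0.4)
        np.fill_diagonal(v, 0.0)
        v[0, 1] = v[1, 0] = 0.05
        v[2, 3] = v[3, 2] = 0.05
        tree = kd.neighbor_joining(kd.DistanceMatrix(ids, v))
        assert _splits(tree) == {frozenset({frozenset({"A", "B"}),
                                            frozenset({"C", "D"})})}

    def test_matches_reference_nj_on_random_matrices(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 6
            coords = rng.random((n, 3))
            d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
            ids = [f"t{i}" for i in range(n)]
            ours = kd.neighbor_joining(kd.DistanceMatrix(ids, d))
            ref = skbio_nj(skbio.DistanceMatrix(d, ids))
            import dendropy
            tns = dendropy.TaxonNamespace()
            a = dendropy.Tree.get(data=ours.as_string(schema="newick"),
                                  schema="newick", taxon_namespace=tns)
            b = dendropy.Tree.get(data=str(ref), schema="newick",
                                  taxon_namespace=tns)
            a.encode_bipartitions()
            b.encode_bipartitions()
            assert dendropy.calculate.treecompare.symmetric_difference(a, b) == 0

    def test_fewer_than_three_taxa_rejected(self):
        dm = kd.DistanceMatrix(["A", "B"], np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(ValueError, match="trivial"):
            kd.neighbor_joining(dm)

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(11)
        coords = rng.random((7, 2))
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        tree = kd.neighbor_joining(
            kd.DistanceMatrix([f"t{i}" for i in range(7)], d))
        assert all(e.length >= 0 for e in tree.preorder_edge_iter()
                   if e.length is not None)


def brute_force_diagnostic(aln, group_a, group_b):
    """Independent column-scan oracle for diagnostic sites."""
    out = []
    for pos in range(aln.length):
        sa = {aln.sequence(s)[pos] for s in group_a} & set("ACGT")
        sb = {aln.sequence(s)[pos] for s in group_b} & set("ACGT")
        if sa and sb and not (sa & sb):
            out.append(pos + 1)
    return out


class TestDiagnosticSites:
    def test_single_fixed_difference(self):
        aln = kd.Alignment(["a1", "a2", "b1", "b2"],
                           ["ACGT", "ACGT", "ACGA", "ACGA"])
        sites = kd.diagnostic_sites(aln, {"a1", "a2"}, {"b1", "b2"})
        assert [(s.position, s.state_a, s.state_b) for s in sites] == [
            (4, frozenset("T"), frozenset("A"))]

    def test_identical_groups_empty(self, tiny_alignment):
        assert kd.diagnostic_sites(tiny_alignment, {"a1"}, {"a2"}) == []

    def test_overlapping_states_not_diagnostic(self):
        aln = kd.Alignment(["a1", "b1", "b2"], ["ACGT", "ACGT", "ACGA"])
        assert kd.diagnostic_sites(aln, {"a1"}, {"b1", "b2"}) == []

    def test_overlapping_groups_rejected(self, tiny_alignment):
        with pytest.raises(ValueError, match="overlap"):
            kd.diagnostic_sites(tiny_alignment, {"a1", "b1"}, {"b1"})

    def test_missing_data_lenient_vs_strict(self):
        aln = kd.Alignment(["a1", "a2", "b1"], ["ACGT", "ACGN", "ACGA"])
        lenient = kd.diagnostic_sites(aln, {"a1", "a2"}, {"b1"})
        assert [s.position for s in lenient] == [4]
        strict = kd.diagnostic_sites(aln, {"a1", "a2"}, {"b1"}, strict=True)
        assert strict == []

    @given(st.integers(5, 30), st.integers(0, 10 ** 6))
    def test_matches_brute_force_on_random_alignments(self, length, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        chars = np.array(list("ACGTN-"))
        seqs = ["".join(rng.choice(chars, size=length, p=[.22, .22, .22, .22, .06, .06]))
                for _ in range(n_a + n_b)]
        ids = [f"s{i}" for i in range(n_a + n_b)]
        aln = kd.Alignment(ids, seqs)
        ga, gb = set(ids[:n_a]), set(ids[n_a:])
        ours = [s.position for s in kd.diagnostic_sites(aln, ga, gb)]
        assert ours == brute_force_diagnostic(aln, ga, gb)

    def test_swap_symmetry(self, tiny_alignment):
        ga, gb = {"a1", "a2"}, {"b1", "b2"}
        fwd = kd.diagnostic_sites(tiny_alignment, ga, gb)
        rev = kd.diagnostic_sites(tiny_alignment, gb, ga)
        assert [(s.position, s.state_a, s.state_b) for s in fwd] == \
               [(s.position, s.state_b, s.state_a) for s in rev]
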