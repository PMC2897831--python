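"""NJ reconstruction, consensus, midpoint rooting, Newick round trips."""

import numpy as np
import pytest
from skbio import DistanceMatrix

import chemophylo as cp

from conftest import bipartitions, random_additive_tree

FOUR_TAXON = DistanceMatrix(
    np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    ),
    ids=["A", "B", "C", "D"],
)


class TestNJ:
    def test_four_taxon_example_exact(self):
        """Additive AB=3 AC=5 AD=6 BC=6 BD=7 CD=7: split AB|CD, lengths 1,2,3,4,1."""
        tree = cp.nj(FOUR_TAXON)
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        internal = [n for n in tree.non_tips(include_self=False)]
        assert internal[0].length == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), ids=list("ABC"))
        tree = cp.nj(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_rejects_small_or_nan(self):
        with pytest.raises(ValueError):
            cp.nj(DistanceMatrix(np.zeros((2, 2)), ids=["A", "B"]))

    @pytest.mark.parametrize("seed", range(15))
    def test_additive_recovery(self, seed):
        """NJ is exact on additive matrices: topology and branch lengths."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        true_tree, dm = random_additive_tree(rng, n)
        est = cp.nj(dm)
        assert bipartitions(est) == bipartitions(true_tree)
        td = est.tip_tip_distances()
        M = np.array([[td[a, b] if a != b else 0 for b in dm.ids] for a in dm.ids])
        assert np.allclose(M, dm.data, atol=1e-9)

    def test_negative_lengths_clamped(self):
        dm = DistanceMatrix(
            np.array([[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 0.5], [9, 9, 0.5, 0]], float),
            ids=list("ABCD"),
        )
        tree = cp.nj(dm)
        assert all((t.length or 0) >= 0 for t in tree.traverse())


class TestConsensus:
    def test_additive_input_consensus_equals_nj(self):
        cons, trees = cp.randomized_consensus(FOUR_TAXON, n_orders=10, seed=11)
        assert bipartitions(cons) == bipartitions(trees[0])
        supports = [n.support for n in cons.non_tips(include_self=False)]
        assert supports == [1.0]

    def test_same_seed_reproducible(self, tmp_path):
        a, _ = cp.randomized_consensus(FOUR_TAXON, n_orders=10, seed=5)
        b, _ = cp.randomized_consensus(FOUR_TAXON, n_orders=10, seed=5)
        pa, pb = tmp_path / "a.nwk", tmp_path / "b.nwk"
        cp.write_newick(a, pa)
        cp.write_newick(b, pb)
        assert pa.read_text() == pb.read_text()

    def test_supports_match_independent_recount(self):
        """Consensus bipartition frequencies re-counted over the input trees."""
        rng = np.random.default_rng(2)
        n = 7
        _, dm = random_additive_tree(rng, n)
        noisy = dm.data + rng.uniform(0, 0.8, size=dm.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        cons, trees = cp.randomized_consensus(
            DistanceMatrix(noisy, ids=dm.ids), n_orders=10, seed=3
        )
        tree_splits = [bipartitions(t) for t in trees]
        for node in cons.non_tips(include_self=False):
            split = frozenset(t.name for t in node.tips())
            ref = sorted(dm.ids)[0]
            if ref in split:
                split = frozenset(dm.ids) - split
            recount = sum(split in s for s in tree_splits) / len(trees)
            assert node.support == pytest.approx(recount)
            assert recount > 0.5

    def test_majority_rule_only_majority_splits(self):
        t1 = cp.read_newick_string("((A,B),(C,D),(E,F));")
        t2 = cp.read_newick_string("((A,B),(C,E),(D,F));")
        t3 = cp.read_newick_string("((A,B),(C,F),(D,E));")
        cons = cp.phylo.majority_rule_consensus([t1, t2, t3])
        # only AB|CDEF is in a majority (all three trees); normalized to the
        # side not containing the reference leaf A
        assert bipartitions(cons) == {frozenset({"C", "D", "E", "F"})}


class TestMidpointRoot:
    def test_four_taxon_midpoint(self):
        tree = cp.nj(FOUR_TAXON)
        rooted = cp.midpoint_root(tree)
        dists = {t.name: rooted.distance(t) for t in rooted.tips()}
        # longest leaf-leaf path is C..D (7); root halfway at 3.5
        assert dists["C"] == pytest.approx(3.5)
        assert dists["D"] == pytest.approx(3.5)

    def test_symmetric_chain_bisected(self):
        t = cp.read_newick_string("(A:2,B:2);")
        rooted = cp.midpoint_root(t)
        d = {x.name: rooted.distance(x) for x in rooted.tips()}
        assert d["A"] == pytest.approx(d["B"])

    def test_idempotent_on_balanced_tree(self):
        t = cp.read_newick_string("((A:1,B:1):1,(C:1,D:1):1);")
        r1 = cp.midpoint_root(t)
        r2 = cp.midpoint_root(r1)
        assert bipartitions(r1) == bipartitions(r2)
        d1 = {x.name: r1.distance(x) for x in r1.tips()}
        d2 = {x.name: r2.distance(x) for x in r2.tips()}
        assert d1 == pytest.approx(d2)

    def test_zero_length_tree_warns_but_roots(self, caplog):
        t = cp.read_newick_string("((A:0,B:0):0,C:0);")
        with caplog.at_level("WARNING"):
            rooted = cp.midpoint_root(t)
        assert {x.name for x in rooted.tips()} == {"A", "B", "C"}

    def test_leaf_set_preserved_through_pipeline(self, benchmark):
        cons, _ = cp.randomized_consensus(benchmark["Dlig"], 10, seed=1)
        rooted = cp.midpoint_root(cons)
        assert {t.name for t in rooted.tips()} == set(benchmark["Dlig"].ids)


class TestNewick:
    def test_round_trip_lengths(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:2):1,C:3);\n")
        tree = cp.read_newick(p)
        out = tmp_path / "o.nwk"
        cp.write_newick(tree, out)
        again = cp.read_newick(out)
        td1, td2 = tree.tip_tip_distances(), again.tip_tip_distances()
        for a in "ABC":
            for b in "ABC":
                if a != b:
                    assert td1[a, b] == pytest.approx(td2[a, b], abs=1e-9)

    def test_supports_round_trip(self, tmp_path):
        cons, _ = cp.randomized_consensus(FOUR_TAXON, 10, seed=0)
        p = tmp_path / "c.nwk"
        cp.write_newick(cons, p)
        again = cp.read_newick(p)
        sup = [n.support for n in again.non_tips(include_self=False)]
        assert sup == [1.0]

    def test_malformed_newick_raises(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:2):1,C:3;")  # unbalanced
        with pytest.raises(Exception):
            cp.read_newick(p)


def test_nj_matches_dendropy_on_noisy_matrix():
    """Independent cross-check of the NJ implementation (dendropy)."""
    import dendropy

    rng = np.random.default_rng(17)
    n = 8
    _, dm = random_additive_tree(rng, n)
    noisy = dm.data + rng.uniform(0, 0.3, size=dm.shape)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0)
    dmx = np.round(noisy, 6)

    mine = cp.nj(DistanceMatrix(dmx, ids=dm.ids))

    csv = "," + ",".join(dm.ids) + "\n"
    for i, lab in enumerate(dm.ids):
        csv += lab + "," + ",".join(str(x) for x in dmx[i]) + "\n"
    import io
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
    ref = pdm.nj_tree()
    ref_newick = ref.as_string("newick").replace("'", "")
    import tempfile, os
    fd, path = tempfile.mkstemp(suffix=".nwk")
    os.write(fd, ref_newick.encode())
    os.close(fd)
    ref_tree = cp.read_newick(path)
    os.unlink(path)
    assert bipartitions(mine) == bipartitions(ref_tree)
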