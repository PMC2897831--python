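"""Orphanization rules, nearest-class prediction, retrieval AUC."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

import chemophylo as cp
from chemophylo.chem_io import TargetClass
from chemophylo.deorphan import NearestProfileClassifier, curve_from_ranks, orphanize
from chemophylo.profiles import FrequencyMatrix


@pytest.fixture
def tiny():
    """3 classes x 4 substructures with controlled frequent-class structure.

    Class sizes 10; support threshold 0.3 -> a pattern is 'frequent' in a
    class when >= 3 of its 10 ligands contain it.
    """
    codes = ["s_only_A()", "s_shared()", "s_B()", "s_C()"]
    F = FrequencyMatrix(
        df=pd.DataFrame(
            {
                "A": [0.5, 0.8, 0.1, 0.0],
                "B": [0.1, 0.6, 0.9, 0.2],
                "C": [0.0, 0.4, 0.1, 0.7],
            },
            index=codes,
        )
    )
    classes = [
        TargetClass(t, tuple(f"{t}{i}" for i in range(10))) for t in ("A", "B", "C")
    ]
    # occurrence consistent with the frequencies above
    occurrence = {
        code: {
            f"{t}{i}"
            for t in ("A", "B", "C")
            for i in range(int(round(F.df.loc[code, t] * 10)))
        }
        for code in codes
    }
    return F, classes, occurrence


class TestOrphanize:
    def test_exclusive_substructure_dropped(self, tiny):
        F, classes, occ = tiny
        red = orphanize(F, classes, occ, "A")
        # s_only_A is frequent (>=30%) only in A -> removed with the A column
        assert "s_only_A()" not in red.substructure_codes
        assert red.target_ids == ["B", "C"]

    def test_shared_substructure_kept(self, tiny):
        F, classes, occ = tiny
        red = orphanize(F, classes, occ, "A")
        assert "s_shared()" in red.substructure_codes

    def test_other_columns_bit_identical(self, tiny):
        F, classes, occ = tiny
        red = orphanize(F, classes, occ, "A")
        for t in ("B", "C"):
            assert (red.df[t] == F.df.loc[red.substructure_codes, t]).all()

    def test_unknown_orphan(self, tiny):
        F, classes, occ = tiny
        with pytest.raises(KeyError):
            orphanize(F, classes, occ, "Z")


class TestNearestProfileClassifier:
    def test_exact_binary_column_match(self):
        df = pd.DataFrame({"A": [1.0, 0.0], "B": [0.0, 1.0]})
        clf = NearestProfileClassifier().fit(df)
        assert clf.predict([[1, 0]])[0] == "A"
        d = clf.decision_function([[1, 0]])
        assert d[0, 0] == 0.0 and d[0, 1] == pytest.approx(np.sqrt(2))

    def test_argmin_matches_brute_force(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.random((6, 4)), columns=list("ABCD"))
        clf = NearestProfileClassifier().fit(df)
        X = rng.integers(0, 2, size=(10, 6)).astype(float)
        preds = clf.predict(X)
        for x, p in zip(X, preds):
            dists = {t: np.linalg.norm(x - df[t].to_numpy()) for t in df.columns}
            assert p == min(sorted(dists), key=lambda t: dists[t])

    def test_tie_breaks_lexicographic(self):
        df = pd.DataFrame({"B": [1.0], "A": [1.0]})
        clf = NearestProfileClassifier().fit(df)
        assert clf.predict([[0.0]])[0] == "A"

    def test_sklearn_protocol(self):
        clf = NearestProfileClassifier()
        assert clf.get_params() == {}
        df = pd.DataFrame({"A": [1.0, 0.0], "B": [0.0, 1.0]})
        clf.fit(df)
        with pytest.raises(ValueError, match="features"):
            clf.predict([[1, 0, 0]])


class TestRetrievalCurve:
    def test_best_case_auc_one(self):
        c = curve_from_ranks("o", [1, 1, 1], n_neighbors=5)
        assert (c.y == 1.0).all() and c.auc == 1.0

    def test_worst_case_closed_form(self):
        n_classes = 6  # N receptors incl. orphan -> 5 neighbors
        c = curve_from_ranks("o", [5, 5], n_neighbors=5)
        assert c.auc == pytest.approx(1 / 5)

    def test_monotone_and_ends_at_one(self):
        c = curve_from_ranks("o", [2, 4, 1, 4], n_neighbors=4)
        assert (np.diff(c.y) >= 0).all()
        assert c.y[-1] == 1.0

    def test_uniform_rank_expectation(self):
        """Monte-Carlo: uniform ranks give mean AUC = N / (2(N-1))."""
        rng = np.random.default_rng(123)
        n_neighbors = 9  # N = 10 receptors
        aucs = [
            curve_from_ranks("o", [int(rng.integers(1, n_neighbors + 1))], n_neighbors).auc
            for _ in range(10_000)
        ]
        expected = 10 / (2 * 9)
        assert np.mean(aucs) == pytest.approx(expected, abs=3 * np.std(aucs) / 100)

    def test_trapezoid_mode_differs_but_close(self):
        ranks = [1, 2, 2, 3]
        a = curve_from_ranks("o", ranks, 4, auc_mode="mean_step").auc
        b = curve_from_ranks("o", ranks, 4, auc_mode="trapezoid").auc
        assert a != b
        assert abs(a - b) < 0.2


class TestLeaveOneOut:
    def test_two_class_degenerate(self, smi):
        """With 2 non-orphan classes the curve is a step; AUC is the k=1 fraction average."""
        mols = (
            [smi("c1ccccc1CCN", f"A{i}") for i in range(20)]
            + [smi("CCCCCCCCO", f"B{i}") for i in range(20)]
            + [smi("c1ccccc1CCN", f"C{i}") for i in range(10)]
            + [smi("CCCCCCCCO", f"C{i}") for i in range(10, 20)]
        )
        classes = [TargetClass(t, tuple(f"{t}{i}" for i in range(20))) for t in "ABC"]
        by_id = {m.mol_id: m for m in mols}
        results = [
            cp.mine_frequent([by_id[m] for m in c.mol_ids], 0.3, target_id=c.target_id)
            for c in classes
        ]
        F, occ = cp.merge_and_profile(results, classes, mols)
        Dseq = DistanceMatrix(
            np.array([[0, 0.1, 0.5], [0.1, 0, 0.6], [0.5, 0.6, 0]]), ids=list("ABC")
        )
        curve = cp.leave_one_out("C", F, classes, occ, Dseq)
        # C's ligands are exact copies of A's and B's: all predictions resolve
        assert set(curve.ranks) <= {1, 2}
        assert curve.y[-1] == 1.0
        assert curve.auc == pytest.approx((curve.y[0] + 1.0) / 2)

    def test_orphan_missing_from_sequence_space(self, tiny):
        F, classes, occ = tiny
        Dseq = DistanceMatrix(np.array([[0, 1], [1, 0]]), ids=["A", "B"])
        with pytest.raises(KeyError):
            cp.leave_one_out("C", F, classes, occ, Dseq)

    def test_determinism(self, benchmark):
        a = cp.leave_one_out(
            "F1R1", benchmark["F"], benchmark["classes"],
            benchmark["occurrence"], benchmark["Dseq"],
        )
        b = cp.leave_one_out(
            "F1R1", benchmark["F"], benchmark["classes"],
            benchmark["occurrence"], benchmark["Dseq"],
        )
        assert a.ranks == b.ranks and a.auc == b.auc


class TestRunAllOrphans:
    def test_summary_fractions(self, benchmark):
        summary, curves = cp.run_all_orphans(
            benchmark["F"], benchmark["classes"],
            benchmark["occurrence"], benchmark["Dseq"],
        )
        assert len(summary) == len(benchmark["classes"])
        frac = summary.attrs["fraction_auc_gt_0.5"]
        assert frac == (summary["auc"] > 0.5).mean()
        assert all(0 < c.auc <= 1 for c in curves.values())

    def test_plot_curves_writes_gallery(self, tmp_path):
        curves = {
            "X": curve_from_ranks("X", [1, 2], 3),
            "Y": curve_from_ranks("Y", [3, 3], 3),
        }
        paths = cp.deorphan.plot_curves(curves, tmp_path)
        assert len(paths) == 2
        # ordered by descending AUC: X first
        assert "X" in paths[0].name and "Y" in paths[1].name
        assert (tmp_path / "X_curve.tsv").exists()
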