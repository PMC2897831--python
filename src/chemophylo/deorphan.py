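"""Leave-one-out virtual de-orphanization.

Each receptor in turn is treated as an orphan: its column is removed
from the frequency matrix and every substructure that is frequent
*only* in that class is dropped from the row set.  Each of the orphan's
ligands is then assigned to the nearest remaining class by Euclidean
distance between the ligand's binary substructure-presence vector and
the class frequency columns.  The predicted class's rank in sequence
space (1 = sequence-nearest receptor to the orphan) yields a cumulative
retrieval curve over k = 1..N−1 included neighbors; the relative AUC is
the mean height of that curve (1.0 = every ligand lands in the
sequence-nearest class, 1/(N−1) = every ligand in the farthest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .chem_io import TargetClass
from .mining import absolute_support
from .profiles import FrequencyMatrix

logger = logging.getLogger(__name__)


@dataclass
class RetrievalCurve:
    """Cumulative identified-ligand fractions for one pretended orphan."""

    orphan_id: str
    ranks: list[int]  # per-ligand rank of the predicted class in sequence space
    y: np.ndarray  # cumulative fraction at k = 1..N-1
    auc: float
    n_ligands: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(1, len(self.y) + 1), "cumulative_fraction": self.y}
        )


class NearestProfileClassifier(BaseEstimator, ClassifierMixin):
    """Nearest-class prediction in substructure space.

    Fit on a frequency matrix (rows = substructures, columns = classes);
    predict from binary presence vectors over the same rows.  The
    predicted class minimizes the Euclidean distance between the vector
    and the class frequency column; ties break lexicographically by
    class id (and are logged).
    """

    def fit(self, X: pd.DataFrame, y=None) -> "NearestProfileClassifier":
        if X.shape[1] < 1:
            raise ValueError("need at least one class column")
        order = np.argsort(X.columns)
        self.classes_ = np.asarray(X.columns)[order]
        self.profiles_ = X.to_numpy()[:, order]
        self.n_features_in_ = X.shape[0]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "profiles_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} substructure features, got {X.shape[1]}"
            )
        diff = X[:, :, None] - self.profiles_[None, :, :]
        return np.sqrt((diff**2).sum(axis=1))

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        idx = d.argmin(axis=1)
        n_ties = (d == d[np.arange(len(idx)), idx][:, None]).sum(axis=1)
        if (n_ties > 1).any():
            logger.info(
                "%d molecule(s) tied between classes; lexicographic tie-break applied",
                int((n_ties > 1).sum()),
            )
        return self.classes_[idx]


def orphanize(
    F: FrequencyMatrix,
    classes: list[TargetClass],
    occurrence: dict[str, set[str]],
    orphan_id: str,
    min_support_fraction: float = 0.30,
) -> FrequencyMatrix:
    """Remove the orphan column and its exclusively-frequent substructures.

    A substructure is dropped when the orphan is the *only* class in
    which its within-class frequency reaches the mining support
    threshold; all remaining entries are reused from the persistent
    occurrence table (no re-mining).
    """
    if orphan_id not in F.target_ids:
        raise KeyError(f"unknown orphan target {orphan_id!r}")
    sizes = {c.target_id: len(c.mol_ids) for c in classes}
    # within-class occurrence counts are exactly frequency * class size
    counts = np.rint(
        F.df.to_numpy() * np.array([sizes[t] for t in F.target_ids])[None, :]
    )
    thresholds = np.array(
        [absolute_support(min_support_fraction, sizes[t]) for t in F.target_ids]
    )
    frequent = counts >= thresholds[None, :]
    orphan_col = F.target_ids.index(orphan_id)
    only_in_orphan = frequent[:, orphan_col] & (
        frequent.sum(axis=1) == frequent[:, orphan_col].astype(int)
    )
    keep_rows = [c for c, drop in zip(F.substructure_codes, only_in_orphan) if not drop]
    reduced = F.df.loc[keep_rows, [t for t in F.target_ids if t != orphan_id]]
    return FrequencyMatrix(df=reduced)


def _presence_vector(
    mol_id: str, codes: list[str], occurrence: dict[str, set[str]]
) -> np.ndarray:
    return np.array([1.0 if mol_id in occurrence[c] else 0.0 for c in codes])


def predict_class(
    mol_id: str, Freduced: FrequencyMatrix, occurrence: dict[str, set[str]]
) -> str:
    """Nearest class for one molecule; wrapper over the classifier."""
    clf = NearestProfileClassifier().fit(Freduced.df)
    x = _presence_vector(mol_id, Freduced.substructure_codes, occurrence)
    if x.sum() == 0:
        logger.info("molecule %s contains none of the substructures (uninformative)", mol_id)
    return str(clf.predict([x])[0])


def leave_one_out(
    orphan_id: str,
    F: FrequencyMatrix,
    classes: list[TargetClass],
    occurrence: dict[str, set[str]],
    Dseq,
    min_support_fraction: float = 0.30,
    auc_mode: str = "mean_step",
) -> RetrievalCurve:
    """Retrieval curve and relative AUC for one pretended orphan."""
    if orphan_id not in Dseq.ids:
        raise KeyError(f"orphan {orphan_id!r} missing from the sequence distance matrix")
    others = [t for t in F.target_ids if t != orphan_id]
    if len(others) < 2:
        raise ValueError("need at least two non-orphan classes")
    Freduced = orphanize(F, classes, occurrence, orphan_id, min_support_fraction)
    # ascending sequence distance; ties broken lexicographically
    ranked = sorted(others, key=lambda t: (Dseq[orphan_id, t], t))
    rank_of = {t: k + 1 for k, t in enumerate(ranked)}

    clf = NearestProfileClassifier().fit(Freduced.df)
    orphan_class = next(c for c in classes if c.target_id == orphan_id)
    codes = Freduced.substructure_codes
    X = np.array([_presence_vector(m, codes, occurrence) for m in orphan_class.mol_ids])
    predictions = clf.predict(X)
    ranks = [rank_of[p] for p in predictions]
    return curve_from_ranks(orphan_id, ranks, len(others), auc_mode)


def curve_from_ranks(
    orphan_id: str, ranks: list[int], n_neighbors: int, auc_mode: str = "mean_step"
) -> RetrievalCurve:
    """Cumulative retrieval curve and relative AUC from per-ligand ranks.

    ``y[k]`` is the fraction of ligands whose predicted class sits within
    the ``k`` sequence-nearest receptors; the relative AUC is the mean of
    ``y`` over k = 1..n_neighbors (a trapezoid variant is available).
    """
    if not ranks:
        raise ValueError("no ligand ranks")
    if any(not 1 <= r <= n_neighbors for r in ranks):
        raise ValueError("rank outside 1..n_neighbors")
    counts = np.zeros(n_neighbors)
    for r in ranks:
        counts[r - 1] += 1
    y = np.cumsum(counts) / len(ranks)
    if auc_mode == "mean_step":
        auc = float(y.mean())
    elif auc_mode == "trapezoid":
        auc = float(np.trapezoid(y, dx=1.0) / (n_neighbors - 1)) if n_neighbors > 1 else float(y[0])
    else:
        raise ValueError(f"unknown auc_mode {auc_mode!r}")
    return RetrievalCurve(
        orphan_id=orphan_id, ranks=list(ranks), y=y, auc=auc, n_ligands=len(ranks)
    )


def run_all_orphans(
    F: FrequencyMatrix,
    classes: list[TargetClass],
    occurrence: dict[str, set[str]],
    Dseq,
    min_support_fraction: float = 0.30,
    auc_mode: str = "mean_step",
) -> tuple[pd.DataFrame, dict[str, RetrievalCurve]]:
    """Leave-one-out over every receptor.

    Returns a summary table (orphan_id, n_ligands, auc) and the
    per-orphan curves; the summary's attrs carry the fractions of
    receptors with AUC above 0.5 and 0.7.
    """
    curves: dict[str, RetrievalCurve] = {}
    for tid in F.target_ids:
        curves[tid] = leave_one_out(
            tid, F, classes, occurrence, Dseq, min_support_fraction, auc_mode
        )
    summary = pd.DataFrame(
        {
            "orphan_id": list(curves),
            "n_ligands": [c.n_ligands for c in curves.values()],
            "auc": [c.auc for c in curves.values()],
        }
    )
    summary.attrs["fraction_auc_gt_0.5"] = float((summary["auc"] > 0.5).mean())
    summary.attrs["fraction_auc_gt_0.7"] = float((summary["auc"] > 0.7).mean())
    return summary, curves


def plot_curves(curves: dict[str, RetrievalCurve], out_dir: str | Path) -> list[Path]:
    """One step plot per orphan (diagonal = random); TSVs always written.

    The gallery is ordered by descending AUC.
    """
    if not curves:
        raise ValueError("no curves to plot")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    ordered = sorted(curves.values(), key=lambda c: -c.auc)
    for gallery_idx, curve in enumerate(ordered):
        curve.to_frame().to_csv(out_dir / f"{curve.orphan_id}_curve.tsv", sep="\t", index=False)
        fig, ax = plt.subplots(figsize=(4, 4))
        k = np.arange(1, len(curve.y) + 1)
        ax.step(k, curve.y, where="post", color="crimson")
        ax.plot([0, len(curve.y)], [0, 1], color="steelblue", lw=1)
        ax.set_xlabel("number of included receptors")
        ax.set_ylabel("ligands identified")
        ax.set_title(curve.orphan_id)
        ax.text(0.95, 0.05, f"AUC = {curve.auc:.4f}", ha="right", transform=ax.transAxes)
        ax.set_ylim(0, 1.02)
        fig.tight_layout()
        p = out_dir / f"{gallery_idx:03d}_{curve.orphan_id}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
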