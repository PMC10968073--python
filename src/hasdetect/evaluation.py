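"""Study designs, confusion-matrix metrics, ROC/AUC and summary tables.

Three study designs probe generalization across cohorts:

* **Study #1** -- leave-one-group-out with the sham controls (G3) always in
  training: test on G4, G2, G1 in turn.
* **Study #2** -- the same three schemes with G3 excluded everywhere.
* **Study #3** -- class-stratified 5-fold cross-validation over all groups
  (80/20 split, fixed seed so folds are identical across detectors).

Metrics follow the conventional confusion-matrix definitions; *selectivity*
is the true-negative rate (specificity) and precision is TP/(TP+FP) -- the
definition every reference table value satisfies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .core import GROUPS

LOOCV_TEST_ORDER = ("G4", "G2", "G1")


@dataclass
class StudyScheme:
    """One train/test partition of a segment dataset.

    ``train_idx``/``test_idx`` index rows of the manifest the scheme was
    built from.  Counts are (total, seizures, non_seizures).
    """

    study_id: int
    scheme: int
    train_groups: tuple[str, ...]
    test_groups: tuple[str, ...]
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test sets must be disjoint")

    def counts(self, labels: np.ndarray) -> dict:
        def side(idx):
            lab = labels[idx]
            n_seiz = int((lab == 1).sum())
            return (idx.size, n_seiz, idx.size - n_seiz)

        train, test = side(self.train_idx), side(self.test_idx)
        return {
            "train": train,
            "test": test,
            "training_to_testing_ratio": train[0] / test[0],
        }


@dataclass
class ConfusionMetrics:
    """TP/FP/FN/TN counts and the derived percentages.

    Undefined ratios (zero denominator) are NaN, never 0 or 100.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    auc: float = np.nan

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def selectivity(self) -> float:
        return _pct(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def accuracy(self) -> float:
        return _pct(self.tp + self.tn, self.total)

    def as_row(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "TN": self.tn,
            "sensitivity": round(self.sensitivity, 2),
            "selectivity": round(self.selectivity, 2),
            "precision": round(self.precision, 2),
            "accuracy": round(self.accuracy, 2),
            "auc": self.auc,
        }


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else float("nan")


@dataclass
class RocCurve:
    """A threshold-swept ROC curve with its trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def interpolate(self, fpr_grid: np.ndarray) -> np.ndarray:
        return np.interp(fpr_grid, self.fpr, self.tpr)


def _labels_array(manifest: pd.DataFrame) -> np.ndarray:
    return (manifest["label"].to_numpy() == "HAS").astype(int)


def build_loocv_schemes(
    manifest: pd.DataFrame, include_sham: bool = True
) -> list[StudyScheme]:
    """The three leave-one-group-out schemes of study #1 or #2.

    Tests on G4, G2, G1 in turn; G3 (sham, no seizures) joins the training
    side when ``include_sham`` (study #1) and is dropped entirely otherwise
    (study #2).  Raises if the manifest is missing a required group.
    """
    present = set(manifest["group"])
    needed = set(GROUPS) if include_sham else set(GROUPS) - {"G3"}
    missing = needed - present
    if missing:
        raise ValueError(f"manifest is missing groups {sorted(missing)}")
    groups = manifest["group"].to_numpy()
    study_id = 1 if include_sham else 2
    schemes = []
    for i, test_g in enumerate(LOOCV_TEST_ORDER, start=1):
        train_groups = tuple(
            g for g in GROUPS if g != test_g and (include_sham or g != "G3")
        )
        schemes.append(
            StudyScheme(
                study_id=study_id,
                scheme=i,
                train_groups=train_groups,
                test_groups=(test_g,),
                train_idx=np.flatnonzero(np.isin(groups, train_groups)),
                test_idx=np.flatnonzero(groups == test_g),
            )
        )
    return schemes


def build_kfold(manifest: pd.DataFrame, k: int = 5, seed: int = 0) -> list[StudyScheme]:
    """Class-stratified k-fold schemes over all groups (study #3).

    With counts divisible by k the folds are exactly equal; otherwise the
    remainder goes to the earliest folds, per class.  A fixed seed makes
    fold membership identical across runs and detectors.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = _labels_array(manifest)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    schemes = []
    for i, (train_idx, test_idx) in enumerate(skf.split(np.zeros(y.size), y), start=1):
        schemes.append(
            StudyScheme(
                study_id=3,
                scheme=i,
                train_groups=tuple(GROUPS),
                test_groups=(f"fold_{i}",),
                train_idx=train_idx,
                test_idx=test_idx,
            )
        )
    return schemes


def confusion(labels, predictions) -> ConfusionMetrics:
    """Confusion counts for binary labels/predictions (1 = HAS)."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(((labels == 1) & (predictions == 1)).sum())
    fp = int(((labels == 0) & (predictions == 1)).sum())
    fn = int(((labels == 1) & (predictions == 0)).sum())
    tn = int(((labels == 0) & (predictions == 0)).sum())
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def roc_auc(scores, labels) -> RocCurve:
    """ROC by threshold sweep over the unique scores, trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_sk_auc(fpr, tpr)))


def mean_roc(
    curves: list[RocCurve], n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertical averaging over a fixed FPR grid: (grid, mean TPR, SD TPR)."""
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.vstack([c.interpolate(grid) for c in curves])
    return grid, tprs.mean(axis=0), tprs.std(axis=0, ddof=1 if len(curves) > 1 else 0)


def summarize_study(metrics: list[ConfusionMetrics]) -> dict:
    """Mean +/- SD of accuracy and AUC over a study's schemes/folds."""
    if not metrics:
        raise ValueError("need at least one metric row")
    acc = np.array([m.accuracy for m in metrics])
    aucs = np.array([m.auc for m in metrics])
    sd = lambda v: float(v.std(ddof=1)) if v.size > 1 else 0.0
    return {
        "n": len(metrics),
        "accuracy_mean": float(acc.mean()),
        "accuracy_sd": sd(acc),
        "auc_mean": float(np.nanmean(aucs)) if np.isfinite(aucs).any() else np.nan,
        "auc_sd": sd(aucs[np.isfinite(aucs)]) if np.isfinite(aucs).any() else np.nan,
    }


def results_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-scheme metric rows into a reporting DataFrame."""
    return pd.DataFrame(rows)


@dataclass
class EnergyThresholdBaseline:
    """Trivial reference classifier: threshold on segment RMS.

    The threshold maximizing training accuracy over midpoints of the sorted
    training RMS values is kept.  High-amplitude artifacts in the non-HAS
    class are exactly what this baseline cannot reject, which is why the
    CNNs must outperform it.
    """

    threshold: float = field(default=np.nan)

    @staticmethod
    def _rms(segments) -> np.ndarray:
        return np.array([np.sqrt(np.mean(np.square(s.samples))) for s in segments])

    def fit(self, segments, labels) -> "EnergyThresholdBaseline":
        r = self._rms(segments)
        y = np.asarray(labels).astype(int)
        order = np.argsort(r)
        r_sorted = r[order]
        cand = np.concatenate(
            [[r_sorted[0] - 1.0], (r_sorted[:-1] + r_sorted[1:]) / 2, [r_sorted[-1] + 1.0]]
        )
        accs = [((r > t).astype(int) == y).mean() for t in cand]
        self.threshold = float(cand[int(np.argmax(accs))])
        return self

    def predict(self, segments) -> np.ndarray:
        return (self._rms(segments) > self.threshold).astype(int)
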