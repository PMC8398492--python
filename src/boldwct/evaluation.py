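"""Classification metrics and validation protocols.

Five per-class metrics, reported as percentages:

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    F-score     = 2 * precision * sensitivity / (precision + sensitivity)

Multi-class results are macro-averaged: each class is binarised one-vs-rest,
the five metrics are computed per class, and the unweighted mean over classes
is reported.  Splitting protocols: stratified hold-out (default
0.7/0.15/0.15), stratified k-fold, and leave-one-site-out, each either at
image level (default, mirroring per-image training-set counts) or at subject
level (all of a subject's images stay in one partition; image-level splits of
multi-image subjects can leak subject identity across partitions).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

METRIC_NAMES = ("precision", "sensitivity", "specificity", "accuracy", "f_score")


class EvaluationError(ValueError):
    """Raised for invalid metric inputs or infeasible split requests."""


def f_score_from(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (same units in and out)."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


@dataclasses.dataclass
class MetricEntry:
    """Five metrics in percent; ``undefined`` lists any 0/0 reported as 0."""

    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    f_score: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> MetricEntry:
    """Metrics of one binary confusion (positive = patient class)."""
    counts = (tp, fp, fn, tn)
    if any(c < 0 for c in counts):
        raise EvaluationError("confusion counts must be non-negative")
    if sum(counts) == 0:
        raise EvaluationError("empty confusion: no evaluated items")

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return 100.0 * num / den

    precision = ratio(tp, tp + fp, "precision")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    accuracy = 100.0 * (tp + tn) / sum(counts)
    f = f_score_from(precision, sensitivity)
    if precision + sensitivity == 0:
        undefined.append("f_score")
    return MetricEntry(precision, sensitivity, specificity, accuracy, f,
                       undefined=tuple(undefined))


@dataclasses.dataclass
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise EvaluationError(f"counts must be {k}x{k} for {k} classes")
        if np.any(self.counts < 0):
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @staticmethod
    def from_predictions(
        y_true: Sequence[int], y_pred: Sequence[int], classes: Sequence[str]
    ) -> "ConfusionMatrix":
        k = len(classes)
        counts = np.zeros((k, k), dtype=int)
        for t, p in zip(np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)):
            counts[t, p] += 1
        return ConfusionMatrix(counts, list(classes))

    def one_vs_rest(self, class_index: int) -> tuple[int, int, int, int]:
        """(tp, fp, fn, tn) of the binarised problem for one class."""
        c = self.counts
        tp = int(c[class_index, class_index])
        fp = int(c[:, class_index].sum() - tp)
        fn = int(c[class_index, :].sum() - tp)
        tn = int(c.sum() - tp - fp - fn)
        return tp, fp, fn, tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclasses.dataclass
class MetricsReport:
    """Per-class metrics plus their unweighted (macro) average."""

    per_class: dict[str, MetricEntry]
    macro: MetricEntry
    confusion: Optional[ConfusionMatrix] = None

    def to_frame(self, ndigits: int = 1) -> pd.DataFrame:
        rows = {name: entry.rounded(ndigits) for name, entry in self.per_class.items()}
        rows["macro"] = self.macro.rounded(ndigits)
        return pd.DataFrame(rows).T

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "per_class": {k: v.as_dict() for k, v in self.per_class.items()},
            "macro": self.macro.as_dict(),
        }
        if self.confusion is not None:
            payload["confusion"] = {
                "classes": self.confusion.classes,
                "counts": self.confusion.counts.tolist(),
            }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path


def macro_average(
    confusion: ConfusionMatrix, zero_support: str = "zero"
) -> MetricsReport:
    """One-vs-rest metrics per class and their unweighted mean.

    Classes with zero support (no true items) are flagged; they enter the
    macro mean as zeros with ``zero_support="zero"`` or are dropped from it
    with ``"exclude"``.
    """
    if len(confusion.classes) < 2:
        raise EvaluationError("macro-averaging needs >= 2 classes")
    if zero_support not in ("zero", "exclude"):
        raise EvaluationError("zero_support must be 'zero' or 'exclude'")

    per_class: dict[str, MetricEntry] = {}
    included: list[MetricEntry] = []
    for i, name in enumerate(confusion.classes):
        tp, fp, fn, tn = confusion.one_vs_rest(i)
        entry = binary_metrics(tp, fp, fn, tn)
        support = tp + fn
        if support == 0:
            entry.undefined = tuple(set(entry.undefined) | {"zero_support"})
            if zero_support == "exclude":
                per_class[name] = entry
                continue
        per_class[name] = entry
        included.append(entry)
    if not included:
        raise EvaluationError("no class with support to average")

    macro = MetricEntry(
        *(float(np.mean([getattr(e, m) for e in included])) for m in METRIC_NAMES)
    )
    return MetricsReport(per_class=per_class, macro=macro, confusion=confusion)


# ---------------------------------------------------------------------------
# split plans
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SplitPlan:
    """Partition of item indices: hold-out sets, k folds, or per-site rounds."""

    kind: str  # "holdout" | "kfold" | "loso"
    unit: str  # "image" | "subject"
    seed: Optional[int] = None
    train: Optional[np.ndarray] = None
    val: Optional[np.ndarray] = None
    test: Optional[np.ndarray] = None
    folds: Optional[list[np.ndarray]] = None
    rounds: Optional[list[tuple[str, np.ndarray, np.ndarray]]] = None  # (site, train, test)


def _units(labels: np.ndarray, unit_groups: Optional[np.ndarray]) -> tuple[list, np.ndarray]:
    """Collapse items to split units; returns (unit ids, unit labels)."""
    if unit_groups is None:
        return list(range(labels.size)), labels
    unit_ids: list = []
    unit_labels: list = []
    seen: dict = {}
    for g, lab in zip(unit_groups, labels):
        if g not in seen:
            seen[g] = lab
            unit_ids.append(g)
            unit_labels.append(lab)
        elif seen[g] != lab:
            raise EvaluationError(f"unit {g!r} carries more than one class label")
    return unit_ids, np.asarray(unit_labels)


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    exact = [n * r for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    rem = n - sum(base)
    order = np.argsort([-(e - b) for e, b in zip(exact, base)], kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base


def make_holdout_split(
    labels: Sequence,
    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
    unit_groups: Optional[Sequence] = None,
    seed: int = 0,
) -> SplitPlan:
    """Stratified train/validation/test split.

    Sizes per class follow ``ratios`` by largest remainder (within +-1 of
    exact).  With ``unit_groups`` given (e.g. subject ids), whole units are
    assigned to one partition.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise EvaluationError(f"ratios must sum to 1, got {ratios}")
    labels = np.asarray(labels)
    groups = None if unit_groups is None else np.asarray(unit_groups)
    unit_ids, unit_labels = _units(labels, groups)

    rng = np.random.default_rng(seed)
    part_units: list[list] = [[], [], []]
    for cls in np.unique(unit_labels):
        members = [u for u, lab in zip(unit_ids, unit_labels) if lab == cls]
        order = rng.permutation(len(members))
        sizes = _largest_remainder(len(members), ratios)
        cut1, cut2 = sizes[0], sizes[0] + sizes[1]
        for pos, j in enumerate(order):
            bucket = 0 if pos < cut1 else (1 if pos < cut2 else 2)
            part_units[bucket].append(members[j])

    def expand(units: list) -> np.ndarray:
        if groups is None:
            return np.asarray(sorted(units), dtype=int)
        wanted = set(units)
        return np.asarray([i for i, g in enumerate(groups) if g in wanted], dtype=int)

    return SplitPlan(
        kind="holdout",
        unit="image" if unit_groups is None else "subject",
        seed=seed,
        train=expand(part_units[0]),
        val=expand(part_units[1]),
        test=expand(part_units[2]),
    )


def kfold_plan(
    labels: Sequence,
    k: int,
    unit_groups: Optional[Sequence] = None,
    seed: int = 0,
) -> SplitPlan:
    """Stratified k-fold plan: folds are disjoint and cover all items."""
    labels = np.asarray(labels)
    if k < 2 or k > labels.size:
        raise EvaluationError(f"k={k} infeasible for {labels.size} items")
    groups = None if unit_groups is None else np.asarray(unit_groups)
    unit_ids, unit_labels = _units(labels, groups)

    rng = np.random.default_rng(seed)
    fold_units: list[list] = [[] for _ in range(k)]
    for cls in np.unique(unit_labels):
        members = [u for u, lab in zip(unit_ids, unit_labels) if lab == cls]
        if len(members) < k:
            raise EvaluationError(
                f"class {cls!r} has {len(members)} units, fewer than k={k}"
            )
        order = rng.permutation(len(members))
        for pos, j in enumerate(order):
            fold_units[pos % k].append(members[j])

    def expand(units: list) -> np.ndarray:
        if groups is None:
            return np.asarray(sorted(units), dtype=int)
        wanted = set(units)
        return np.asarray([i for i, g in enumerate(groups) if g in wanted], dtype=int)

    return SplitPlan(
        kind="kfold",
        unit="image" if unit_groups is None else "subject",
        seed=seed,
        folds=[expand(u) for u in fold_units],
    )


def leave_one_site_out(
    sites: Sequence,
    labels: Sequence,
    required_classes: Optional[Sequence] = None,
) -> SplitPlan:
    """One train/test round per site that contains every required class.

    Sites lacking a required class never serve as the held-out test site but
    always remain in training.
    """
    sites = np.asarray(sites)
    labels = np.asarray(labels)
    if sites.size != labels.size:
        raise EvaluationError("sites and labels must have equal length")
    required = set(required_classes) if required_classes is not None else set(labels.tolist())

    rounds: list[tuple[str, np.ndarray, np.ndarray]] = []
    for site in pd.unique(sites):
        present = set(labels[sites == site].tolist())
        if not required <= present:
            continue
        test = np.flatnonzero(sites == site)
        train = np.flatnonzero(sites != site)
        rounds.append((str(site), train, test))
    if not rounds:
        raise EvaluationError("no site contains all required classes")
    return SplitPlan(kind="loso", unit="image", rounds=rounds)


# ---------------------------------------------------------------------------
# aggregation / reporting
# ---------------------------------------------------------------------------

def aggregate_entries(
    entries: dict[str, MetricEntry], ndigits: int = 1
) -> pd.DataFrame:
    """Per-round rows plus a mean +- SD row (layout of cross-validated reports)."""
    rows = {name: entry.rounded(ndigits) for name, entry in entries.items()}
    frame = pd.DataFrame(rows).T
    means = frame.mean(axis=0)
    sds = frame.std(axis=0, ddof=1) if len(frame) > 1 else frame.iloc[0] * 0.0
    frame.loc["mean"] = means.round(ndigits)
    frame.loc["sd"] = sds.round(ndigits)
    return frame


def format_mean_sd(frame: pd.DataFrame, ndigits: int = 1) -> dict[str, str]:
    """``{"accuracy": "86.8 ± 0.7", ...}`` from an aggregate frame."""
    return {
        col: f"{frame.loc['mean', col]:.{ndigits}f} ± {frame.loc['sd', col]:.{ndigits}f}"
        for col in frame.columns
    }
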