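"""Feature construction, decision-tree classification and validation.

The classifier operates on four circadian attributes per subject: the
TAP-L5h mid-sleep phase marker, the TAP-M10h mid-wake phase marker, the
TAP relative amplitude, and the CFI of estimated sleep.  A published
fixed tree with four cut values separates healthy controls, three
insomnia subtypes and DSPD; trees can also be induced from labelled data
by greedy information-gain splitting on Fayyad-Irani MDLP cut points.

Validation follows the standard diagnostic formulas on one-vs-rest
confusion counts: sensitivity TP/(TP+FN), precision TP/(TP+FP) (called
"accuracy"/predictive value in parts of the clinical literature), their
harmonic mean F1, specificity TN/(TN+FP), false-positive rate
1 - specificity, and the ROC AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .nonparam import NonParamIndexes
from .synthetic import CLASSES

logger = logging.getLogger(__name__)

ATTRIBUTES = ("tap_l5h", "tap_m10h", "tap_ra", "sleep_cfi")


@dataclass(frozen=True)
class FeatureVector:
    """The four selected circadian attributes of one subject."""

    subject_id: str
    tap_l5h: float  # minutes from midnight, [0, 1440)
    tap_m10h: float
    tap_ra: float
    sleep_cfi: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "subject_id":
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{self.subject_id}: non-finite {f.name}")
        for name in ("tap_l5h", "tap_m10h"):
            if not 0 <= getattr(self, name) < 1440:
                raise ValueError(f"{self.subject_id}: {name} outside [0, 1440)")


@dataclass(frozen=True)
class FixedTreeSpec:
    """Published decision-tree cut values.

    Boundary semantics are literal: "later than" cuts are strict (a value
    exactly at 5:27 or 16:07 goes to the not-later branch), the RA cut is
    strict "<" and the CFI cut inclusive ">=".
    """

    l5h_cut: float = 327.0  # 5:27
    m10h_cut: float = 967.0  # 16:07
    ra_cut: float = 0.629
    cfi_cut: float = 0.852


def classify_fixed_tree(fv: FeatureVector, spec: FixedTreeSpec | None = None) -> str:
    """Assign one of the five diagnostic labels with the published tree.

    Delayed mid-sleep (TAP-L5h later than the 5:27 cut) splits off the
    phase-delayed branch, where a late activation peak (TAP-M10h later
    than 16:07) means DSPD and an earlier one onset insomnia.  Otherwise
    low TAP-RA (< 0.629) means maintenance insomnia, and among the rest
    robust sleep rhythms (sleep-CFI >= 0.852) mean control, the remainder
    mild insomnia.
    """
    spec = spec or FixedTreeSpec()
    if fv.tap_l5h > spec.l5h_cut:
        return "dspd" if fv.tap_m10h > spec.m10h_cut else "onset_insomnia"
    if fv.tap_ra < spec.ra_cut:
        return "maintenance_insomnia"
    return "control" if fv.sleep_cfi >= spec.cfi_cut else "mild_insomnia"


def build_feature_table(
    summaries: dict[str, dict[str, NonParamIndexes]],
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per subject with the four tree attributes (+ label if known).

    ``summaries`` maps subject id -> variable role -> NonParamIndexes and
    must contain the ``tap`` and ``sleep`` summaries for every subject.
    """
    rows = []
    for subject_id, per_var in summaries.items():
        for needed in ("tap", "sleep"):
            if needed not in per_var:
                raise ValueError(f"subject {subject_id}: missing {needed} summary")
        tap, sleep = per_var["tap"], per_var["sleep"]
        fv = FeatureVector(
            subject_id=subject_id,
            tap_l5h=tap.l5h,
            tap_m10h=tap.m10h,
            tap_ra=tap.RA,
            sleep_cfi=sleep.CFI,
        )
        row = {
            "subject_id": fv.subject_id,
            "tap_l5h": fv.tap_l5h,
            "tap_m10h": fv.tap_m10h,
            "tap_ra": fv.tap_ra,
            "sleep_cfi": fv.sleep_cfi,
        }
        if labels is not None:
            row["label"] = labels[subject_id]
        rows.append(row)
    return pd.DataFrame(rows)


def _entropy(labels: np.ndarray) -> float:
    """Shannon entropy in bits of a label array."""
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _split_gain(y: np.ndarray, left_mask: np.ndarray) -> float:
    n = y.size
    n_left = int(left_mask.sum())
    if n_left in (0, n):
        return 0.0
    h = _entropy(y)
    h_left = _entropy(y[left_mask])
    h_right = _entropy(y[~left_mask])
    return h - (n_left / n) * h_left - ((n - n_left) / n) * h_right


def _mdlp_accept(y: np.ndarray, left_mask: np.ndarray, gain: float) -> bool:
    """Fayyad-Irani minimum-description-length criterion for one cut."""
    n = y.size
    k = len(np.unique(y))
    k1 = len(np.unique(y[left_mask]))
    k2 = len(np.unique(y[~left_mask]))
    delta = math.log2(3**k - 2) - (
        k * _entropy(y) - k1 * _entropy(y[left_mask]) - k2 * _entropy(y[~left_mask])
    )
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def mdl_discretize(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Fayyad-Irani MDLP cut points for one continuous attribute.

    Candidate cuts are midpoints between adjacent distinct values; a cut
    is accepted iff its information gain exceeds the MDL coding cost, and
    the procedure recurses on both sides.  Degenerate inputs (single
    class, single value) give an empty list.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    cuts: list[float] = []

    def recurse(v: np.ndarray, y: np.ndarray) -> None:
        if v.size < 2 or len(np.unique(y)) < 2:
            return
        boundaries = np.nonzero(np.diff(v) > 0)[0]
        best = None
        for b in boundaries:
            mask = np.zeros(v.size, dtype=bool)
            mask[: b + 1] = True
            gain = _split_gain(y, mask)
            if best is None or gain > best[0]:
                best = (gain, b, mask)
        if best is None:
            return
        gain, b, mask = best
        if not _mdlp_accept(y, mask, gain):
            return
        cuts.append((v[b] + v[b + 1]) / 2.0)
        recurse(v[: b + 1], y[: b + 1])
        recurse(v[b + 1 :], y[b + 1 :])

    recurse(v, y)
    return sorted(cuts)


def score_attributes(
    table: pd.DataFrame,
    attributes: tuple[str, ...] = ATTRIBUTES,
    label_col: str = "label",
) -> pd.DataFrame:
    """Information gain, one-way ANOVA F and Pearson chi-squared per attribute.

    Information gain and chi-squared operate on the MDLP-discretized
    attribute (gain in bits: H(class) - H(class | bin)); ANOVA uses the
    raw values grouped by class.
    """
    y = table[label_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("attribute scoring needs at least two classes")
    rows = []
    for attr in attributes:
        x = table[attr].to_numpy(dtype=float)
        cuts = mdl_discretize(x, y)
        bins = np.searchsorted(cuts, x)
        gain = _entropy(y) - sum(
            (np.sum(bins == b) / y.size) * _entropy(y[bins == b])
            for b in np.unique(bins)
        )
        groups = [x[y == c] for c in np.unique(y)]
        f_stat = stats.f_oneway(*groups).statistic if len(np.unique(x)) > 1 else 0.0
        if not np.isfinite(f_stat):
            f_stat = 0.0
        if len(np.unique(bins)) > 1:
            contingency = pd.crosstab(y, bins).to_numpy()
            chi2 = stats.chi2_contingency(contingency, correction=False).statistic
        else:
            chi2 = 0.0
        rows.append(
            {
                "attribute": attr,
                "information_gain": float(gain),
                "anova_F": float(f_stat),
                "chi_squared": float(chi2),
            }
        )
    return pd.DataFrame(rows).set_index("attribute")


@dataclass
class TreeNode:
    """Binary decision node (or leaf when ``label`` is set)."""

    label: str | None = None
    attribute: str | None = None
    cut: float | None = None
    left: "TreeNode | None" = None  # attribute <= cut
    right: "TreeNode | None" = None
    class_counts: dict[str, int] = field(default_factory=dict)

    def predict_one(self, row: pd.Series) -> str:
        node = self
        while node.label is None:
            node = node.left if row[node.attribute] <= node.cut else node.right
        return node.label

    def score_one(self, row: pd.Series, positive: str) -> float:
        """Leaf class-probability estimate for ``positive``."""
        node = self
        while node.label is None:
            node = node.left if row[node.attribute] <= node.cut else node.right
        total = sum(node.class_counts.values())
        if total == 0:
            return 0.0
        return node.class_counts.get(positive, 0) / total


def _majority(y: np.ndarray) -> str:
    classes, counts = np.unique(y, return_counts=True)
    best = counts.max()
    tied = set(classes[counts == best])
    for label in CLASSES:  # ties broken by class enumeration order
        if label in tied:
            return label
    return sorted(tied)[0]


def induce_tree(
    table: pd.DataFrame,
    attributes: tuple[str, ...] = ATTRIBUTES,
    label_col: str = "label",
    max_depth: int | None = None,
    min_leaf: int = 1,
) -> TreeNode:
    """Greedy top-down tree induction on MDLP cut points by information gain.

    Ties between candidate splits are broken by attribute order then by
    the lower cut value; leaves take the majority class (ties by class
    enumeration order).  A single-class input yields a single leaf.
    """
    x = {a: table[a].to_numpy(dtype=float) for a in attributes}
    y = table[label_col].to_numpy()

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        sub_y = y[idx]
        counts = {c: int((sub_y == c).sum()) for c in np.unique(sub_y)}
        leaf = TreeNode(label=_majority(sub_y), class_counts=counts)
        if (
            len(counts) < 2
            or (max_depth is not None and depth >= max_depth)
            or idx.size < 2 * min_leaf
        ):
            return leaf
        best = None  # (gain, attr_pos, cut, mask)
        for pos, attr in enumerate(attributes):
            sub_x = x[attr][idx]
            for cut in mdl_discretize(sub_x, sub_y):
                mask = sub_x <= cut
                if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
                    continue
                gain = _split_gain(sub_y, mask)
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, pos, cut, mask)
        if best is None or best[0] <= 0:
            return leaf
        _, pos, cut, mask = best
        node = TreeNode(
            attribute=attributes[pos],
            cut=float(cut),
            left=grow(idx[mask], depth + 1),
            right=grow(idx[~mask], depth + 1),
            class_counts=counts,
        )
        return node

    return grow(np.arange(len(table)), 0)


def predict(tree: TreeNode, table: pd.DataFrame) -> pd.Series:
    """Predicted label per row of a feature table."""
    return table.apply(tree.predict_one, axis=1)


@dataclass
class ConfusionMatrix:
    """One-vs-rest counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int


def compute_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Diagnostic rates from one-vs-rest counts.

    Follows the textbook formulas exactly; "precision" is the positive
    predictive value TP/(TP+FP), also called accuracy in parts of the
    clinical validation literature.  Zero denominators yield NaN.
    """

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    sensitivity = ratio(cm.tp, cm.tp + cm.fn)
    precision = ratio(cm.tp, cm.tp + cm.fp)
    specificity = ratio(cm.tn, cm.tn + cm.fp)
    if sensitivity + precision > 0:
        f1 = 2 * sensitivity * precision / (sensitivity + precision)
    else:
        f1 = float("nan")
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "specificity": specificity,
        "f1": f1,
        "false_positive_rate": 1.0 - specificity,
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals the probability that a random positive outranks a random
    negative, ties counting one half — identical to the trapezoidal area
    under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both positive and negative cases")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ValidationReport:
    """Cross-validated per-class confusion counts and derived metrics."""

    per_class: pd.DataFrame
    overall_accuracy: float
    predictions: pd.DataFrame
    folds: pd.Series
    k: int
    seed: int


def cross_validate(
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    model: str = "fixed",
    tree_spec: FixedTreeSpec | None = None,
    label_col: str = "label",
) -> ValidationReport:
    """Stratified k-fold validation of the fixed or induced tree.

    Folds are stratified by class when every class has at least ``k``
    members, otherwise plain shuffled folds are used with a warning.
    Per-class confusion counts accumulate over held-out folds; the fixed
    tree ("fixed") needs no fitting, "induced" refits a tree per fold.
    """
    n = len(table)
    if k < 2 or k > n:
        raise ValueError("k must lie in [2, n]")
    y = table[label_col].to_numpy()
    class_counts = pd.Series(y).value_counts()
    if (class_counts >= k).all():
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(table, y)
    else:
        logger.warning("some class has fewer than k members; folds unstratified")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(table)

    preds = pd.Series(index=table.index, dtype=object)
    folds = pd.Series(index=table.index, dtype=int)
    score_cols: dict[str, pd.Series] = {
        c: pd.Series(index=table.index, dtype=float) for c in np.unique(y)
    }
    for fold_id, (train_idx, test_idx) in enumerate(split_iter):
        test = table.iloc[test_idx]
        if model == "fixed":
            spec = tree_spec or FixedTreeSpec()
            fold_pred = test.apply(
                lambda row: classify_fixed_tree(
                    FeatureVector(
                        str(row.get("subject_id", row.name)),
                        row["tap_l5h"],
                        row["tap_m10h"],
                        row["tap_ra"],
                        row["sleep_cfi"],
                    ),
                    spec,
                ),
                axis=1,
            )
            for c in score_cols:
                score_cols[c].iloc[test_idx] = (fold_pred == c).astype(float)
        elif model == "induced":
            tree = induce_tree(table.iloc[train_idx], label_col=label_col)
            fold_pred = predict(tree, test)
            for c in score_cols:
                score_cols[c].iloc[test_idx] = test.apply(
                    lambda row: tree.score_one(row, c), axis=1
                )
        else:
            raise ValueError("model must be 'fixed' or 'induced'")
        preds.iloc[test_idx] = fold_pred.to_numpy()
        folds.iloc[test_idx] = fold_id

    rows = []
    for c in np.unique(y):
        pos = y == c
        hit = preds.to_numpy() == c
        cm = ConfusionMatrix(
            tp=int((pos & hit).sum()),
            fp=int((~pos & hit).sum()),
            tn=int((~pos & ~hit).sum()),
            fn=int((pos & ~hit).sum()),
        )
        metrics = compute_metrics(cm)
        try:
            auc = roc_auc(score_cols[c].to_numpy(), pos)
        except ValueError:
            auc = float("nan")
        rows.append(
            {"class": c, "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn}
            | metrics
            | {"auc": auc}
        )
    per_class = pd.DataFrame(rows).set_index("class")
    overall = float((preds.to_numpy() == y).mean())
    predictions = pd.DataFrame(
        {"label": y, "predicted": preds.to_numpy(), "fold": folds.to_numpy()},
        index=table.index,
    )
    return ValidationReport(per_class, overall, predictions, folds, k, seed)
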