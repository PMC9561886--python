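"""Evaluation statistics: localization error and failure rate, 3-class
confusion matrices with one-vs-rest sensitivity/specificity/precision/F1,
ICC(2,1) inter-rater agreement, one-way ANOVA, and k-fold bookkeeping.

Conventions: confusion matrices are printed rows = predicted, columns =
true, class order (femoral, middle, tibial).  A localization *failure* is an
error strictly larger than 10 mm; the error rate is failures / total cases.
Metrics with a zero denominator are reported as NaN ("undefined"), never 0
or 1 — reader matrices are sparse enough for silent zeros to mislead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from aclloc.classify import SIDES, SideClass

__all__ = [
    "ConfusionMatrix3",
    "MetricsReport",
    "LocalizationStats",
    "FoldSplit",
    "IccResult",
    "euclidean_error",
    "failure_flag",
    "localization_stats",
    "confusion",
    "class_metrics",
    "icc_single_absolute",
    "anova_oneway",
    "fivefold_split",
    "cross_validate",
    "format_p",
]

FAILURE_THRESHOLD_MM = 10.0


def euclidean_error(pred, truth) -> float:
    """L2 distance (mm) between predicted and true landmark."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(truth))):
        raise ValueError("landmarks must be finite")
    return float(np.linalg.norm(pred - truth))


def failure_flag(error: float, threshold: float = FAILURE_THRESHOLD_MM) -> bool:
    """True iff the error is strictly larger than the threshold (10 mm default)."""
    if error < 0:
        raise ValueError("error must be >= 0")
    return error > threshold


@dataclass(frozen=True)
class LocalizationStats:
    errors: np.ndarray
    mean: float
    sd: float
    failures: int
    error_rate: float
    threshold: float = FAILURE_THRESHOLD_MM


def localization_stats(errors, threshold: float = FAILURE_THRESHOLD_MM) -> LocalizationStats:
    """Mean +/- sample SD of the per-case errors, plus the failure/error rate."""
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ValueError("errors must be non-empty")
    failures = int(np.sum(errors > threshold))
    sd = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    return LocalizationStats(
        errors=errors,
        mean=float(errors.mean()),
        sd=sd,
        failures=failures,
        error_rate=failures / errors.size,
        threshold=threshold,
    )


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 counts, rows = predicted, columns = true, order (femoral, middle, tibial)."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.shape != (3, 3) or np.any(c < 0):
            raise ValueError("counts must be a 3x3 non-negative matrix")
        if c.sum() == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __str__(self) -> str:
        head = "Predict\\truth\t" + "\t".join(SIDES)
        rows = [
            f"{SIDES[i]}\t" + "\t".join(str(int(v)) for v in self.counts[i]) for i in range(3)
        ]
        return "\n".join([head] + rows)


def _side_name(x) -> str:
    return x.value if isinstance(x, SideClass) else str(x)


def confusion(preds, truths) -> ConfusionMatrix3:
    """Counts[i][j] = number of cases predicted class i with true class j."""
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have equal length")
    idx = {s: i for i, s in enumerate(SIDES)}
    counts = np.zeros((3, 3), dtype=int)
    for p, t in zip(preds, truths):
        counts[idx[_side_name(p)], idx[_side_name(t)]] += 1
    return ConfusionMatrix3(counts=counts)


@dataclass(frozen=True)
class MetricsReport:
    """Per-class one-vs-rest metrics plus overall accuracy; NaN = undefined."""

    per_class: dict
    overall_accuracy: float

    def as_rows(self):
        for side in SIDES:
            m = self.per_class[side]
            yield side, m["sensitivity"], m["specificity"], m["precision"], m["f1"]


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def class_metrics(cm: ConfusionMatrix3) -> MetricsReport:
    """One-vs-rest reduction of a 3-class confusion matrix.

    For class c: TP = cm[c][c]; FP = other entries of row c (predicted c,
    true other); FN = other entries of column c; TN = the rest.  Then
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    precision = TP/(TP+FP), F1 = TP/(TP + 0.5 (FP+FN)); overall accuracy is
    trace/total.
    """
    c = cm.counts
    total = cm.total
    per_class = {}
    for i, side in enumerate(SIDES):
        tp = int(c[i, i])
        fp = int(c[i].sum()) - tp
        fn = int(c[:, i].sum()) - tp
        tn = total - tp - fp - fn
        per_class[side] = {
            "sensitivity": _safe_div(tp, tp + fn),
            "specificity": _safe_div(tn, tn + fp),
            "precision": _safe_div(tp, tp + fp),
            "f1": _safe_div(tp, tp + 0.5 * (fp + fn)),
        }
    return MetricsReport(per_class=per_class, overall_accuracy=np.trace(c) / total)


# ---------------------------------------------------------------------------
# Agreement and group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci95: tuple
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int
    defined: bool = True


def icc_single_absolute(ratings, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): single measure, two-way random effects, absolute agreement.

    ``ratings`` is subjects x raters with no missing cells.  The estimate
    comes from the two-way ANOVA decomposition; the 95% CI uses the standard
    F-based interval (McGraw & Wong).  A matrix with zero total variance has
    no defined ICC and is returned flagged with NaN.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be subjects x raters with >= 2 of each")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must not contain missing cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if ss_total <= 1e-12:
        return IccResult(
            icc=float("nan"), ci95=(float("nan"), float("nan")),
            ms_rows=msr, ms_cols=msc, ms_error=mse,
            n_subjects=n, n_raters=k, defined=False,
        )

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    # F-based CI with Satterthwaite degrees of freedom (McGraw & Wong 1996)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lower, upper = float("nan"), float("nan")
    return IccResult(
        icc=float(icc), ci95=(float(lower), float(upper)),
        ms_rows=float(msr), ms_cols=float(msc), ms_error=float(mse),
        n_subjects=n, n_raters=k,
    )


def anova_oneway(*groups):
    """Classical one-way ANOVA; returns (F statistic, p value)."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate groups: all observations identical")
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def format_p(p: float, alpha_floor: float = 0.01) -> str:
    """Display a p value at 4 decimals with a '<0.01'-style floor."""
    if p < alpha_floor:
        return f"<{alpha_floor:g}"
    return f"{p:.4f}"


# ---------------------------------------------------------------------------
# Cross-validation bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldSplit:
    assignments: dict  # case id -> fold index
    k: int

    def fold_ids(self, fold: int):
        return [cid for cid, f in self.assignments.items() if f == fold]


def fivefold_split(case_ids, k: int = 5, seed: int = 0, stratify=None) -> FoldSplit:
    """Seeded shuffle then round-robin assignment into k folds.

    Folds are disjoint, exhaustive, and their sizes differ by at most one.
    ``stratify`` (optional, parallel to ``case_ids``) balances a class label
    across folds.
    """
    case_ids = list(case_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(case_ids):
        raise ValueError(f"k={k} exceeds number of cases {len(case_ids)}")
    if len(set(case_ids)) != len(case_ids):
        raise ValueError("case ids must be unique")
    rng = np.random.default_rng(seed)
    assignments = {}
    counter = 0
    if stratify is None:
        order = rng.permutation(len(case_ids))
        for pos in order:
            assignments[case_ids[pos]] = counter % k
            counter += 1
    else:
        stratify = list(stratify)
        if len(stratify) != len(case_ids):
            raise ValueError("stratify must parallel case_ids")
        for label in sorted(set(map(str, stratify))):
            members = [i for i, s in enumerate(stratify) if str(s) == label]
            for pos in rng.permutation(len(members)):
                assignments[case_ids[members[pos]]] = counter % k
                counter += 1
    return FoldSplit(assignments=assignments, k=k)


@dataclass
class CrossValResult:
    split: FoldSplit
    fold_stats: list
    pooled_stats: LocalizationStats
    confusion: ConfusionMatrix3
    metrics: MetricsReport
    fold_failures: list = field(default_factory=list)


def cross_validate(
    cases,
    fit_predict,
    k: int = 5,
    seed: int = 0,
    threshold: float = FAILURE_THRESHOLD_MM,
    stratify_by_side: bool = False,
) -> CrossValResult:
    """k-fold cross-validation of a localization method on phantom cases.

    ``fit_predict(train_cases, test_cases)`` returns one predicted physical
    point per test case (in order).  Predictions are pooled over folds:
    per-fold and pooled localization stats plus the pooled side-classification
    confusion matrix and metrics are reported.  A per-fold failure (an
    exception from ``fit_predict``) is recorded and that fold is skipped.
    """
    from aclloc.classify import AclAxis, classify_case

    cases = list(cases)
    if len(cases) < k:
        raise ValueError("dataset smaller than k")
    split = fivefold_split(
        [c.case_id for c in cases],
        k=k,
        seed=seed,
        stratify=[c.gt.side for c in cases] if stratify_by_side else None,
    )
    by_id = {c.case_id: c for c in cases}
    fold_stats, fold_failures = [], []
    pooled_errors, pred_sides, true_sides = [], [], []
    for fold in range(k):
        test_ids = sorted(split.fold_ids(fold))
        train_cases = [c for c in cases if split.assignments[c.case_id] != fold]
        test_cases = [by_id[cid] for cid in test_ids]
        try:
            points = list(fit_predict(train_cases, test_cases))
        except Exception as exc:  # recorded, not fatal: mirrors per-fold bookkeeping
            fold_failures.append((fold, repr(exc)))
            continue
        errors = []
        for case, point in zip(test_cases, points):
            err = euclidean_error(point, case.gt.rupture_point)
            errors.append(err)
            axis = AclAxis(case.gt.femoral_center, case.gt.tibial_center)
            pred_sides.append(classify_case(np.asarray(point), axis).value)
            true_sides.append(case.gt.side)
        pooled_errors.extend(errors)
        fold_stats.append(localization_stats(errors, threshold))
    if not pooled_errors:
        raise RuntimeError(f"all folds failed: {fold_failures}")
    cm = confusion(pred_sides, true_sides)
    return CrossValResult(
        split=split,
        fold_stats=fold_stats,
        pooled_stats=localization_stats(pooled_errors, threshold),
        confusion=cm,
        metrics=class_metrics(cm),
        fold_failures=fold_failures,
    )
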