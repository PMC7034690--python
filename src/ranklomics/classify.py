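"""Classifiers, leave-one-out validation, stepwise feature selection, metrics.

The modeled study design: features of one panel are combined in a
classifier (logistic regression by default; KNN and SVM for comparison),
the most favorable subset is chosen by stepwise backward elimination using
the leave-one-out (LOO) error as the criterion, and the selected model is
summarized by accuracy / sensitivity / specificity / PPV / NPV.  Note the
selection criterion and the validation are the same LOO loop — faithful to
the original design even though it couples selection and validation; see the
methods note for the caveat.

Within every LOO fold the standardization statistics are learned on the N-1
training cases only, so no information about the held-out case leaks into
its prediction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .core import Dataset
from .errors import (
    AlignmentError,
    DegenerateFoldError,
    DegenerateMatrixError,
    ParameterError,
    SchemaError,
)

logger = logging.getLogger(__name__)


@dataclass
class ClassifierSpec:
    """Classifier family and hyperparameters.

    kind: 'logistic' (max-likelihood, unpenalized; small ridge fallback on
    separation), 'knn' (k neighbors) or 'svm' (RBF kernel, cost C, Platt
    probabilities).  Features are standardized per fold when ``standardize``.
    """

    kind: str = "logistic"
    k: int = 5
    kernel: str = "rbf"
    cost: float = 1.0
    threshold: float = 0.5
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("logistic", "knn", "svm"):
            raise ParameterError(f"unknown classifier kind {self.kind!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ParameterError(f"threshold must be in (0, 1), got {self.threshold}")


@dataclass
class LooResult:
    """Per-case LOO probabilities/predictions plus the selection trace."""

    probabilities: np.ndarray
    predictions: np.ndarray
    selected_features: list[str]
    trace: list[dict] = field(default_factory=list)
    flagged_folds: list[int] = field(default_factory=list)
    error_rate: float = float("nan")


@dataclass
class PerformanceMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn


@dataclass
class SignificanceReport:
    test_name: str
    statistic: float
    p_value: float
    normality_p: tuple[float, float]


def _make_model(spec: ClassifierSpec, penalized: bool = False):
    if spec.kind == "logistic":
        if penalized:
            return LogisticRegression(C=100.0, max_iter=5000)
        return LogisticRegression(C=np.inf, max_iter=5000)  # plain max-likelihood
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k)
    return SVC(kernel=spec.kernel, C=spec.cost, probability=True, random_state=spec.seed)


def _fit_predict_proba(
    spec: ClassifierSpec, x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Fit on the training fold and return P(mutant) for the test rows.

    Returns (probabilities, flagged): a logistic fit that fails to converge
    (typical under complete separation at this cohort scale) is refitted with
    a small ridge penalty and flagged.
    """
    flagged = False
    model = _make_model(spec)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(x_train, y_train)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            if spec.kind == "logistic":
                model = _make_model(spec, penalized=True)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    model.fit(x_train, y_train)
            flagged = True
    proba = model.predict_proba(x_test)
    pos_col = list(model.classes_).index(1)
    return proba[:, pos_col], flagged


def loo_evaluate(
    data: Dataset, spec: ClassifierSpec, feature_subset: Sequence[str] | None = None
) -> LooResult:
    """Leave-one-out: each case predicted by a model fit on the other N-1.

    Standardization (when enabled) uses training-fold statistics only.
    """
    if feature_subset is None:
        feature_subset = list(data.features.columns)
    feature_subset = list(feature_subset)
    if not feature_subset:
        raise SchemaError("feature subset is empty")
    x = data.subset(feature_subset).features.to_numpy(dtype=float)
    y = data.labels
    n = len(y)
    probs = np.empty(n)
    flagged: list[int] = []
    for i in range(n):
        train = np.arange(n) != i
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise DegenerateFoldError(
                f"training fold {i} contains a single class"
            )
        x_tr = x[train]
        x_te = x[i : i + 1]
        if spec.standardize:
            mu = x_tr.mean(axis=0)
            sd = x_tr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            x_tr = (x_tr - mu) / sd
            x_te = (x_te - mu) / sd
        p, was_flagged = _fit_predict_proba(spec, x_tr, y_tr, x_te)
        probs[i] = p[0]
        if was_flagged:
            flagged.append(i)
    preds = (probs >= spec.threshold).astype(int)
    return LooResult(
        probabilities=probs,
        predictions=preds,
        selected_features=feature_subset,
        flagged_folds=flagged,
        error_rate=float(np.mean(preds != y)),
    )


def _full_data_pvalues(data: Dataset, features: Sequence[str]) -> dict[str, float]:
    """Wald p-values of a full-data logistic fit, for stepwise tie-breaking.

    Falls back to +inf per feature (-> lexicographic tie-break) when the fit
    is degenerate (separation at small N is common).
    """
    import statsmodels.api as sm

    x = data.subset(list(features)).features.to_numpy(dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(data.labels, sm.add_constant(x)).fit(disp=0, maxiter=200)
        pvals = np.asarray(fit.pvalues)[1:]  # drop intercept
        if np.any(~np.isfinite(pvals)):
            raise ValueError("non-finite p-values")
        return dict(zip(features, map(float, pvals)))
    except Exception:
        return {f: float("inf") for f in features}


def stepwise_backward_select(data: Dataset, spec: ClassifierSpec) -> LooResult:
    """Backward elimination under the LOO error criterion.

    Starting from the full panel, each iteration tries removing every
    remaining feature, removes the one whose removal gives the lowest LOO
    error, and stops when no removal strictly lowers the current error.
    Ties are broken toward the feature with the largest full-data Wald
    p-value, then lexicographically.  Returns the best subset along the
    trajectory together with the full elimination trace.
    """
    features = list(data.features.columns)
    if len(features) < 1:
        raise SchemaError("dataset has no features")
    tie_pvals = _full_data_pvalues(data, features) if len(features) > 1 else {}

    current = loo_evaluate(data, spec, features)
    best = current
    trace: list[dict] = [
        {"removed": None, "remaining": list(features), "error": current.error_rate}
    ]
    while len(features) > 1:
        candidates = []
        for f in features:
            remaining = [g for g in features if g != f]
            res = loo_evaluate(data, spec, remaining)
            candidates.append((res.error_rate, f, res))
        min_err = min(c[0] for c in candidates)
        if min_err >= current.error_rate:
            break
        tied = [c for c in candidates if c[0] == min_err]
        # Largest full-model p-value first; name as deterministic fallback.
        tied.sort(key=lambda c: (-tie_pvals.get(c[1], float("inf")), c[1]))
        _, removed, result = tied[0]
        features = [g for g in features if g != removed]
        current = result
        trace.append(
            {"removed": removed, "remaining": list(features), "error": current.error_rate}
        )
        if current.error_rate < best.error_rate:
            best = current
    best.trace = trace
    return best


def nested_loo_evaluate(data: Dataset, spec: ClassifierSpec) -> LooResult:
    """Honest generalization estimate: outer LOO around the whole selection.

    For each case the stepwise backward elimination is re-run on the other
    N-1 cases alone, and the held-out case is predicted by a model fit on
    those N-1 with the subset chosen *without* it.  Slower than
    :func:`stepwise_backward_select` by a factor of N, but the reported
    error is decoupled from the selection.
    """
    x_all = data.features
    y = data.labels
    n = len(y)
    probs = np.empty(n)
    flagged: list[int] = []
    per_fold_subsets: list[dict] = []
    for i in range(n):
        keep = np.arange(n) != i
        inner = Dataset(x_all.iloc[keep], y[keep])
        if len(np.unique(inner.labels)) < 2:
            raise DegenerateFoldError(f"outer fold {i} contains a single class")
        selection = stepwise_backward_select(inner, spec)
        cols = selection.selected_features
        x_tr = inner.features[cols].to_numpy(dtype=float)
        x_te = x_all.iloc[[i]][cols].to_numpy(dtype=float)
        if spec.standardize:
            mu = x_tr.mean(axis=0)
            sd = x_tr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            x_tr = (x_tr - mu) / sd
            x_te = (x_te - mu) / sd
        p, was_flagged = _fit_predict_proba(spec, x_tr, inner.labels, x_te)
        probs[i] = p[0]
        if was_flagged:
            flagged.append(i)
        per_fold_subsets.append({"fold": i, "selected": cols})
    preds = (probs >= spec.threshold).astype(int)
    return LooResult(
        probabilities=probs,
        predictions=preds,
        selected_features=list(x_all.columns),
        trace=per_fold_subsets,
        flagged_folds=flagged,
        error_rate=float(np.mean(preds != y)),
    )


def confusion_metrics(result: LooResult, labels: Sequence[int]) -> PerformanceMetrics:
    """Confusion counts and the five-proportion panel from LOO predictions.

    Undefined ratios (zero denominator) are reported as NaN with a warning.
    """
    labels = np.asarray(labels, dtype=int)
    preds = np.asarray(result.predictions, dtype=int)
    if labels.shape != preds.shape:
        raise AlignmentError(
            f"{preds.size} predictions vs {labels.size} labels"
        )
    tp = int(np.sum((preds == 1) & (labels == 1)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("confusion_metrics: %s undefined (zero denominator)", name)
            return float("nan")
        return num / den

    return PerformanceMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "PPV"),
        npv=ratio(tn, tn + fn, "NPV"),
    )


def feature_significance(values: Sequence[float], labels: Sequence[int]) -> SignificanceReport:
    """Two-group test of one feature, gated by a normality check per class.

    Each class is checked with the Lilliefors-corrected Kolmogorov-Smirnov
    test (the appropriate form when the normal parameters are estimated
    from the sample).  If
    both classes pass at alpha = 0.05 a two-sample Student t test is used,
    otherwise the Mann-Whitney U test; both two-sided.
    """
    from statsmodels.stats.diagnostic import lilliefors

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape:
        raise AlignmentError("values and labels misaligned")
    g0 = values[labels == 0]
    g1 = values[labels == 1]
    if len(g0) < 3 or len(g1) < 3:
        raise ParameterError("need >= 3 cases per class")
    if np.ptp(g0) == 0 and np.ptp(g1) == 0:
        logger.warning("feature_significance: constant feature in both classes")
        return SignificanceReport("degenerate", 0.0, 1.0, (1.0, 1.0))

    def normality_p(g: np.ndarray) -> float:
        if np.ptp(g) == 0:
            return 0.0  # a constant sample is not normal
        try:
            return float(lilliefors(g, dist="norm")[1])
        except Exception:
            return float(stats.kstest(g, "norm", args=(g.mean(), g.std(ddof=1)))[1])

    p0, p1 = normality_p(g0), normality_p(g1)
    if p0 > 0.05 and p1 > 0.05:
        stat, p = stats.ttest_ind(g0, g1)
        name = "t"
    else:
        stat, p = stats.mannwhitneyu(g0, g1, alternative="two-sided")
        name = "mannwhitney"
    return SignificanceReport(name, float(stat), float(p), (p0, p1))


def compare_performance_chi2(
    m1: PerformanceMetrics, m2: PerformanceMetrics
) -> tuple[float, float]:
    """Chi-squared test on the 2x2 correct/incorrect table of two methods."""
    table = np.array(
        [
            [m1.n_correct, m1.n - m1.n_correct],
            [m2.n_correct, m2.n - m2.n_correct],
        ],
        dtype=float,
    )
    if table.sum() == 0:
        raise DegenerateMatrixError("zero-total contingency table")
    if np.array_equal(table[0], table[1]):
        return 0.0, 1.0
    if np.any(table.sum(axis=0) == 0):
        # One outcome never occurs in either method: no discrepancy testable.
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
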