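"""Feature selection, RBF-SVM classification, and model comparison.

The validation scheme reports two regimes side by side: stratified 10-fold
cross-validation on the full sample, and repeated stratified 80/20
train-test splits (1,000 by default) whose per-split test metrics form the
reported mean +- SD distributions and the AUC pool.  Feature scaling is
min-max, refit on the training portion of each split by default so no test
information leaks into the scaler; a global-normalization mode is available
for fidelity with analyses that normalize across all participants first.

Model comparisons: a bootstrap test on pooled AUC distributions between
models, and a likelihood-ratio test on nested logistic regressions for the
added value of a second modality's features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

__all__ = [
    "select_features_anova",
    "confusion_metrics",
    "RocResult",
    "roc_auc",
    "chi2_independence",
    "ClassificationReport",
    "train_eval_svm",
    "bootstrap_auc_compare",
    "ModalityComparison",
    "lrt_modality",
]


def select_features_anova(
    features: pd.DataFrame,
    labels,
    q: float = 0.05,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """One-way ANOVA feature screening with BH-FDR.

    Features listed in ``exclude`` (e.g. those associated with antiseizure
    medication load) are dropped before testing.  Zero-variance features are
    skipped with a warning.  Importance is ``-log10(adjusted p)``.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    cols, fstats, pvals = [], [], []
    for c in features.columns:
        if c in exclude:
            continue
        x = features[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"feature {c!r} contains non-finite values")
        if np.ptp(x) == 0:
            warnings.warn(f"feature {c!r} has zero variance; skipped", stacklevel=2)
            continue
        groups = [x[y == k] for k in classes]
        if min(len(g) for g in groups) < 2:
            raise ValueError("need at least 2 subjects per class")
        F, p = sps.f_oneway(*groups)
        cols.append(c)
        fstats.append(float(F))
        pvals.append(float(p))
    from .stats import fdr_bh

    p_adj, reject = fdr_bh(np.array(pvals), q=q)
    with np.errstate(divide="ignore"):
        importance = -np.log10(p_adj)
    return pd.DataFrame(
        {
            "feature": cols,
            "F": fstats,
            "p": pvals,
            "p_fdr": p_adj,
            "selected": reject,
            "importance": importance,
        }
    ).set_index("feature")


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Sensitivity, specificity, PPV, NPV, accuracy from confusion counts.

    Ratios with zero denominators are reported as NaN (missing), not zero.
    """
    counts = {"tp": tp, "tn": tn, "fp": fp, "fn": fn}
    if any(v < 0 for v in counts.values()):
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("confusion counts sum to zero")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": (tp + tn) / total,
    }


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float


def roc_auc(scores, labels) -> RocResult:
    """ROC curve by threshold sweep, trapezoidal AUC, and Youden point.

    ``labels`` are binary with 1 = positive class; ``scores`` are
    higher-means-more-positive.  The sweep predicts positive when
    ``score >= threshold`` over the unique scores, which handles ties
    identically to the rank (concordance) formulation.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    npos = int(y.sum())
    nneg = y.size - npos
    if npos == 0 or nneg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, th in enumerate(thresholds):
        pred = s >= th
        tpr[i] = np.sum(pred & (y == 1)) / npos
        fpr[i] = np.sum(pred & (y == 0)) / nneg
    auc = float(np.trapezoid(tpr, fpr))
    youden = tpr - fpr
    j = int(np.argmax(youden))
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc,
        youden_threshold=float(thresholds[j]),
        youden_sensitivity=float(tpr[j]),
        youden_specificity=float(1.0 - fpr[j]),
    )


def chi2_independence(table) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def _median_heuristic_gamma(X: np.ndarray) -> float:
    d2 = pdist(X, metric="sqeuclidean")
    med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    return 1.0 / med


def _minmax_fit(train: np.ndarray):
    lo = train.min(axis=0)
    span = train.max(axis=0) - lo
    span[span == 0] = 1.0
    return lo, span


@dataclass
class ClassificationReport:
    cv_fold_accuracy: np.ndarray
    split_metrics: pd.DataFrame
    pooled_confusion: dict
    pooled_metrics: dict
    aucs: np.ndarray
    pooled_roc: RocResult
    chi2: float
    chi2_p: float
    gamma: float
    params: dict = field(default_factory=dict)

    def metric_summary(self) -> pd.DataFrame:
        return self.split_metrics.agg(["mean", "std"]).T


def train_eval_svm(
    features: pd.DataFrame,
    labels,
    C: float = 10.0,
    n_folds: int = 10,
    n_splits: int = 1000,
    test_size: float = 0.2,
    seed: int | None = None,
    scaling: str = "train",
    gamma: float | str = "median",
) -> ClassificationReport:
    """RBF-SVM evaluation with stratified k-fold CV and repeated 80/20 splits.

    Per split: min-max scaling (fit on the training portion, or globally
    with ``scaling="global"``), SVC(C, RBF) fit, confusion counts and
    metrics on the held-out test set, and a per-split AUC from the decision
    scores.  Pooled test scores across splits give the reported ROC, Youden
    point, and chi-square on the pooled confusion table.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size != 2:
        raise ValueError("labels must contain exactly two classes")
    if scaling not in ("train", "global"):
        raise ValueError("scaling must be 'train' or 'global'")
    rng = np.random.default_rng(seed)

    if scaling == "global":
        lo, span = _minmax_fit(X)
        X_global = (X - lo) / span
    else:
        X_global = None

    if isinstance(gamma, str):
        if gamma != "median":
            raise ValueError("gamma must be a float or 'median'")
        ref = X_global if X_global is not None else (X - X.min(axis=0)) / np.where(
            np.ptp(X, axis=0) == 0, 1.0, np.ptp(X, axis=0)
        )
        gamma_val = _median_heuristic_gamma(ref)
    else:
        gamma_val = float(gamma)

    # regime (a): stratified k-fold CV accuracy
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    fold_acc = []
    for tr, te in skf.split(X, y):
        if scaling == "train":
            lo, span = _minmax_fit(X[tr])
            Xtr, Xte = (X[tr] - lo) / span, (X[te] - lo) / span
        else:
            Xtr, Xte = X_global[tr], X_global[te]
        clf = SVC(C=C, kernel="rbf", gamma=gamma_val)
        clf.fit(Xtr, y[tr])
        fold_acc.append(float(np.mean(clf.predict(Xte) == y[te])))

    # regime (b): repeated stratified 80/20 splits
    sss = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_size, random_state=int(rng.integers(2**31))
    )
    rows, aucs = [], []
    pooled_scores, pooled_labels = [], []
    tp = tn = fp = fn = 0
    for tr, te in sss.split(X, y):
        if scaling == "train":
            lo, span = _minmax_fit(X[tr])
            Xtr, Xte = (X[tr] - lo) / span, (X[te] - lo) / span
        else:
            Xtr, Xte = X_global[tr], X_global[te]
        clf = SVC(C=C, kernel="rbf", gamma=gamma_val)
        clf.fit(Xtr, y[tr])
        pred = clf.predict(Xte)
        score = clf.decision_function(Xte)
        yt = y[te]
        tp_i = int(np.sum((pred == 1) & (yt == 1)))
        tn_i = int(np.sum((pred == 0) & (yt == 0)))
        fp_i = int(np.sum((pred == 1) & (yt == 0)))
        fn_i = int(np.sum((pred == 0) & (yt == 1)))
        tp, tn, fp, fn = tp + tp_i, tn + tn_i, fp + fp_i, fn + fn_i
        rows.append(confusion_metrics(tp_i, tn_i, fp_i, fn_i))
        aucs.append(roc_auc(score, yt).auc)
        pooled_scores.append(score)
        pooled_labels.append(yt)

    split_metrics = pd.DataFrame(rows)
    pooled = roc_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    chi2, chi2_p = chi2_independence([[tp, fn], [fp, tn]])
    return ClassificationReport(
        cv_fold_accuracy=np.array(fold_acc),
        split_metrics=split_metrics,
        pooled_confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        pooled_metrics=confusion_metrics(tp, tn, fp, fn),
        aucs=np.array(aucs),
        pooled_roc=pooled,
        chi2=chi2,
        chi2_p=chi2_p,
        gamma=gamma_val,
        params={
            "C": C,
            "n_folds": n_folds,
            "n_splits": n_splits,
            "test_size": test_size,
            "scaling": scaling,
            "seed": seed,
        },
    )


def bootstrap_auc_compare(
    pool_a, pool_b, n_boot: int = 10000, seed: int | None = None
) -> float:
    """Two-sided bootstrap comparison of two AUC pools.

    Each bootstrap draw resamples both pools with replacement and records
    the difference of means; the two-sided p is
    ``min(1, 2 * min(P(diff <= 0), P(diff >= 0)))`` over the empirical
    difference distribution.
    """
    a = np.asarray(pool_a, dtype=float)
    b = np.asarray(pool_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("AUC pools must be non-empty")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    p = 2.0 * min(np.mean(diffs <= 0.0), np.mean(diffs >= 0.0))
    return float(min(1.0, p))


@dataclass
class ModalityComparison:
    deviance_base: float
    deviance_full: float
    delta_deviance: float
    df: int
    p: float
    converged: bool
    note: str = ""


def lrt_modality(base_features: pd.DataFrame, added_features: pd.DataFrame, labels) -> ModalityComparison:
    """Likelihood-ratio test for the added value of a second feature set.

    Nested logistic regressions: base (e.g. EEG-only features) versus full
    (base plus the added modality's features).  Delta deviance is referred
    to chi-square with df = number of added features.  Separation-induced
    non-convergence falls back to a ridge-penalized fit and is flagged.
    """
    import statsmodels.api as sm

    y = np.asarray(labels).astype(float)
    Xb = sm.add_constant(base_features.astype(float), has_constant="add")
    Xf = sm.add_constant(
        pd.concat([base_features.astype(float), added_features.astype(float)], axis=1),
        has_constant="add",
    )
    if Xf.shape[1] <= Xb.shape[1]:
        raise ValueError("added feature set is empty")
    converged = True
    note = ""

    def _independent_columns(X: pd.DataFrame) -> pd.DataFrame:
        # the deviance of a rank-deficient design equals that of any
        # maximal independent column subset; drop collinear columns
        A = X.to_numpy(dtype=float)
        keep = []
        rank = 0
        for j in range(A.shape[1]):
            if np.linalg.matrix_rank(A[:, keep + [j]]) > rank:
                keep.append(j)
                rank += 1
        return X.iloc[:, keep]

    def _deviance(X):
        nonlocal converged, note
        X = _independent_columns(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X)
            try:
                fit = model.fit(disp=0, maxiter=200)
                if not fit.mle_retvals.get("converged", True):
                    raise RuntimeError("no convergence")
                return float(2.0 * (0.0 - fit.llf))
            except Exception:
                converged = False
                note = "penalized (ridge) fallback used due to separation/non-convergence"
                fit = model.fit_regularized(alpha=1e-4, L1_wt=0.0, disp=0, maxiter=500)
                return float(-2.0 * model.loglike(np.asarray(fit.params)))

    dev_base = _deviance(Xb)
    dev_full = _deviance(Xf)
    delta = dev_base - dev_full
    df = Xf.shape[1] - Xb.shape[1]
    p = float(sps.chi2.sf(max(delta, 0.0), df))
    return ModalityComparison(
        deviance_base=dev_base,
        deviance_full=dev_full,
        delta_deviance=delta,
        df=df,
        p=p,
        converged=converged,
        note=note,
    )
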