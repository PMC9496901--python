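"""Endpoint-biopsy outcome modeling.

Procedure, per comparison (a single scan point or a pairwise
scan-to-scan feature difference):

1. univariate screen — each feature is tested for association with the
   binary endpoint via a one-feature logistic regression
   likelihood-ratio test; features with p < 0.05 pass;
2. ranking and decorrelation — surviving features are ranked by
   ascending Welch's t-test p-value between the outcome groups; the
   best is selected and all remaining features with |Pearson r| > 0.85
   against it are dropped; repeat until the pool is empty or ``max_k``
   features are selected (ties broken lexicographically by name);
3. multivariate logistic regression, evaluated by leave-one-out (LOO):
   each patient's probability is predicted from a model refit on the
   others; ROC/AUC, confusion matrix and F1 are computed from the n
   held-out probabilities.

By default the feature selection of steps 1-2 is performed once on the
full cohort and LOO re-estimates only the coefficients ("flat" mode,
optimistically biased); a fully nested mode that redoes selection in
every fold is available.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonSet",
    "ModelResult",
    "build_comparisons",
    "univariate_screen",
    "welch_pvalues",
    "select_features",
    "fit_and_evaluate_loo",
    "confusion_and_f1",
    "run_outcome_model",
]

SCAN_ORDER = ("S1", "S2", "S3", "S4")
COMPARISONS = (
    "S1", "S2", "S3", "S4",
    "S2-S1", "S3-S1", "S4-S1", "S3-S2", "S4-S2", "S4-S3",
)


@dataclass
class ComparisonSet:
    """The ten design matrices (4 scans + 6 deltas) with aligned labels."""

    matrices: dict[str, tuple[pd.DataFrame, pd.Series]]

    def __getitem__(self, name: str) -> tuple[pd.DataFrame, pd.Series]:
        return self.matrices[name]

    def names(self) -> list[str]:
        return list(self.matrices)


@dataclass
class ModelResult:
    """Selected features, fitted model, and LOO evaluation."""

    comparison: str
    selected_features: list[str]
    coefficients: dict[str, float]
    intercept: float
    heldout_probs: pd.Series
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    f1: float
    threshold: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "selected_features": self.selected_features,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "heldout_probs": {str(k): float(v) for k, v in self.heldout_probs.items()},
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "f1": self.f1,
            "threshold": self.threshold,
            "flags": self.flags,
            "roc": {"fpr": self.fpr.tolist(), "tpr": self.tpr.tolist()},
        }


def build_comparisons(table: pd.DataFrame, labels: pd.Series) -> ComparisonSet:
    """Assemble the ten comparison design matrices from the feature table.

    ``table`` is indexed by ``(patient_id, scan_point)``.  Difference
    matrices (later minus earlier scan) include only patients present at
    both scans; their columns carry a ``_d<S_b><S_a>`` suffix (e.g.
    ``GTV_ADC_Mean_dS2S1`` for the S2 - S1 change).  Patients with a
    label but no scans are excluded with a log entry.
    """
    if not set(labels.dropna().unique()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    scan_level = table.index.get_level_values("scan_point")
    per_scan = {
        s: table.xs(s, level="scan_point") for s in SCAN_ORDER if s in scan_level
    }
    orphans = set(labels.index) - set(table.index.get_level_values("patient_id"))
    if orphans:
        logger.warning("patients with labels but no scans excluded: %s", sorted(orphans))
    matrices: dict[str, tuple[pd.DataFrame, pd.Series]] = {}
    for s, X in per_scan.items():
        ids = X.index.intersection(labels.dropna().index)
        matrices[s] = (X.loc[ids], labels.loc[ids].astype(int))
    for sa, sb in itertools.combinations(SCAN_ORDER, 2):
        if sa not in per_scan or sb not in per_scan:
            continue
        name = f"{sb}-{sa}"
        common = per_scan[sb].index.intersection(per_scan[sa].index)
        common = common.intersection(labels.dropna().index)
        delta = per_scan[sb].loc[common] - per_scan[sa].loc[common]
        delta.columns = [f"{c}_d{sb}{sa}" for c in delta.columns]
        matrices[name] = (delta, labels.loc[common].astype(int))
    return ComparisonSet(matrices=matrices)


def _logit_llf(y: np.ndarray, X: np.ndarray, maxiter: int = 200) -> tuple[float, bool]:
    """Maximized log-likelihood of a logistic model, with a clean-fit flag.

    A fit is flagged (clean=False) when the optimizer hit its iteration
    cap or the coefficients diverge, as happens under complete
    separation; the capped likelihood still yields a usable LRT.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, method="lbfgs")
            clean = bool(res.mle_retvals.get("converged", True))
            if np.abs(np.asarray(res.params)).max() > 10:
                clean = False  # separation: MLE runs away on standardized data
            return float(res.llf), clean
        except Exception:  # singular matrix, total separation, ...
            return float("nan"), False


def univariate_screen(X: pd.DataFrame, y: pd.Series, *, maxiter: int = 200) -> pd.DataFrame:
    """Likelihood-ratio p-value of each one-feature logistic model.

    Returns a DataFrame with columns ``p`` and ``flagged`` (capped or
    non-converged fits, e.g. under complete separation, are flagged but
    still yield a finite LRT p-value from the capped likelihood).
    """
    y_arr = np.asarray(y, dtype=float)
    if len(np.unique(y_arr)) < 2:
        raise ValueError("labels must contain both classes")
    n = len(y_arr)
    ll_null, _ = _logit_llf(y_arr, np.ones((n, 1)))
    rows = []
    for col in X.columns:
        x = np.asarray(X[col], dtype=float)
        sd = x.std()
        if not np.isfinite(sd) or sd == 0:
            rows.append({"feature": col, "p": 1.0, "flagged": True})
            continue
        Z = sm.add_constant((x - x.mean()) / sd)
        llf, converged = _logit_llf(y_arr, Z, maxiter=maxiter)
        if not np.isfinite(llf):
            rows.append({"feature": col, "p": 1.0, "flagged": True})
            continue
        lrt = max(2.0 * (llf - ll_null), 0.0)
        rows.append(
            {"feature": col, "p": float(sps.chi2.sf(lrt, 1)), "flagged": not converged}
        )
    return pd.DataFrame(rows).set_index("feature")


def welch_pvalues(X: pd.DataFrame, y: pd.Series) -> pd.Series:
    """Welch's t-test p-value per feature between the two outcome groups."""
    y_arr = np.asarray(y).astype(int)
    a, b = X.loc[y_arr == 1], X.loc[y_arr == 0]
    res = sps.ttest_ind(a, b, equal_var=False, axis=0, nan_policy="omit")
    return pd.Series(np.atleast_1d(res.pvalue), index=X.columns)


def select_features(
    X: pd.DataFrame,
    y: pd.Series,
    *,
    p_pass: float = 0.05,
    r_max: float = 0.85,
    max_k: int = 4,
) -> list[str]:
    """Screen, rank, and decorrelate; returns the ordered selection.

    Deterministic greedy loop: among screened features, repeatedly take
    the lowest-Welch-p feature (lexicographic tie-break) and drop all
    remaining features with |Pearson r| > ``r_max`` against it.
    ``max_k=0`` means unlimited.
    """
    screen = univariate_screen(X, y)
    passed = [c for c in X.columns if screen.loc[c, "p"] < p_pass]
    if not passed:
        logger.info("no feature passed the univariate screen at p < %g", p_pass)
        return []
    pw = welch_pvalues(X[passed], y).fillna(1.0)
    remaining = sorted(passed, key=lambda c: (pw[c], c))
    selected: list[str] = []
    while remaining and (max_k == 0 or len(selected) < max_k):
        best = remaining.pop(0)
        selected.append(best)
        if remaining:
            r = X[remaining].corrwith(X[best]).abs()
            remaining = [c for c in remaining if not (r[c] > r_max)]
    return selected


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


def fit_and_evaluate_loo(
    X_selected: pd.DataFrame,
    y: pd.Series,
    *,
    threshold: float = 0.5,
    comparison: str = "",
) -> ModelResult:
    """Leave-one-out evaluation of the multivariate logistic model.

    Selection is assumed done; every fold refits only the coefficients
    (unpenalized maximum likelihood on training-standardized features;
    complete separation saturates the probabilities and is flagged, not
    shrunk).  A fold whose training set loses one class entirely falls
    back to the training prevalence and is flagged.
    """
    if X_selected.shape[1] < 1:
        raise ValueError("need at least one selected feature")
    y_arr = np.asarray(y).astype(int)
    if len(np.unique(y_arr)) < 2:
        raise ValueError("labels must contain both classes")
    X_arr = np.asarray(X_selected, dtype=float)
    n = len(y_arr)
    probs = np.empty(n)
    flags: list[str] = []
    for i in range(n):
        tr = np.arange(n) != i
        Xt, yt = X_arr[tr], y_arr[tr]
        if len(np.unique(yt)) < 2:
            probs[i] = yt.mean()
            flags.append(f"fold {i}: single-class training set; prior rate used")
            continue
        mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
        sd[sd == 0] = 1.0
        clf = _fit_logistic((Xt - mu) / sd, yt)
        probs[i] = clf.predict_proba(((X_arr[i] - mu) / sd).reshape(1, -1))[0, 1]
    fpr, tpr, thr = roc_curve(y_arr, probs)
    auc = float(roc_auc_score(y_arr, probs))
    confusion, f1 = confusion_and_f1(probs, y_arr, threshold)
    # full-data fit for the reported coefficients, on the original scale
    mu, sd = X_arr.mean(axis=0), X_arr.std(axis=0)
    sd[sd == 0] = 1.0
    clf = _fit_logistic((X_arr - mu) / sd, y_arr)
    beta = clf.coef_[0] / sd
    intercept = float(clf.intercept_[0] - (beta * mu).sum())
    if np.abs(clf.coef_).max() > 30:
        flags.append("full-data fit near-separable: coefficients unstable")
    return ModelResult(
        comparison=comparison,
        selected_features=list(X_selected.columns),
        coefficients=dict(zip(X_selected.columns, beta.astype(float))),
        intercept=intercept,
        heldout_probs=pd.Series(probs, index=X_selected.index),
        fpr=fpr, tpr=tpr, thresholds=thr,
        auc=auc, confusion=confusion, f1=f1, threshold=threshold, flags=flags,
    )


def confusion_and_f1(
    heldout_probs, y, threshold: float = 0.5
) -> tuple[np.ndarray, float]:
    """Confusion matrix ``[[TN, FP], [FN, TP]]`` and F1 at a threshold.

    F1 = 2 TP / (2 TP + FP + FN); undefined (NaN) when the labels
    contain no positives.
    """
    probs = np.asarray(heldout_probs, dtype=float)
    y_arr = np.asarray(y).astype(int)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_arr == 1)))
    fp = int(np.sum((pred == 1) & (y_arr == 0)))
    fn = int(np.sum((pred == 0) & (y_arr == 1)))
    tn = int(np.sum((pred == 0) & (y_arr == 0)))
    if y_arr.sum() == 0:
        return np.array([[tn, fp], [fn, tp]]), float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    return np.array([[tn, fp], [fn, tp]]), float(f1)


def run_outcome_model(
    X: pd.DataFrame,
    y: pd.Series,
    *,
    p_pass: float = 0.05,
    r_max: float = 0.85,
    max_k: int = 4,
    threshold: float = 0.5,
    nested: bool = False,
    comparison: str = "",
) -> ModelResult | None:
    """Full procedure: screen, select, fit, LOO-evaluate.

    Flat mode (default) selects once on the full cohort; nested mode
    redoes the selection inside every LOO fold for an unbiased estimate.
    Returns None when nothing passes the screen.
    """
    X = X.dropna(axis=1, how="any")
    if not nested:
        selected = select_features(X, y, p_pass=p_pass, r_max=r_max, max_k=max_k)
        if not selected:
            return None
        return fit_and_evaluate_loo(
            X[selected], y, threshold=threshold, comparison=comparison
        )
    # nested: per-fold selection + fit; final reported selection is the
    # full-cohort one (for interpretation), probabilities are fully held out
    y_arr = np.asarray(y).astype(int)
    n = len(y_arr)
    probs = np.empty(n)
    flags: list[str] = []
    for i in range(n):
        tr_idx = X.index[np.arange(n) != i]
        Xt, yt = X.loc[tr_idx], y.loc[tr_idx]
        if len(np.unique(yt)) < 2:
            probs[i] = float(np.mean(yt))
            flags.append(f"fold {i}: single-class training set")
            continue
        sel = select_features(Xt, yt, p_pass=p_pass, r_max=r_max, max_k=max_k)
        if not sel:
            probs[i] = float(np.mean(yt))
            flags.append(f"fold {i}: empty selection; prior rate used")
            continue
        Xa = np.asarray(Xt[sel], dtype=float)
        mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
        sd[sd == 0] = 1.0
        clf = _fit_logistic((Xa - mu) / sd, np.asarray(yt).astype(int))
        xi = (np.asarray(X[sel].loc[X.index[i]], dtype=float) - mu) / sd
        probs[i] = clf.predict_proba(xi.reshape(1, -1))[0, 1]
    selected = select_features(X, y, p_pass=p_pass, r_max=r_max, max_k=max_k)
    if not selected:
        return None
    result = fit_and_evaluate_loo(
        X[selected], y, threshold=threshold, comparison=comparison
    )
    fpr, tpr, thr = roc_curve(y_arr, probs)
    confusion, f1 = confusion_and_f1(probs, y_arr, threshold)
    result.heldout_probs = pd.Series(probs, index=X.index)
    result.fpr, result.tpr, result.thresholds = fpr, tpr, thr
    result.auc = float(roc_auc_score(y_arr, probs))
    result.confusion, result.f1 = confusion, f1
    result.flags = result.flags + flags + ["nested LOO"]
    return result
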