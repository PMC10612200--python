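"""Statistical evaluation: ROC/AUC with DeLong CIs, the paired DeLong
test, thresholded classification metrics with Wilson CIs, Youden operating
points, multivariate logistic odds ratios and cohort-comparison tests.

The AUC is the Mann-Whitney statistic (ties counted 1/2); its variance and
the covariance between two models scored on the same patients use DeLong's
structural components, which also gives the two-sided z test comparing two
correlated AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io_formats import ClinicalRecord


class UndefinedAucError(ValueError):
    """AUC requested with only one class present."""


class DegenerateVarianceError(ValueError):
    """DeLong variance of the AUC difference is zero with unequal AUCs."""


# ---------------------------------------------------------------------------
# DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong V10/V01 placement components and the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n  # per positive subject
    v01 = 1.0 - (all_r[m:] - neg_r) / m  # per negative subject
    return float(auc), v10, v01


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    curve: np.ndarray  # (k, 2) ordered (fpr, tpr)
    se: float


def roc_auc(scores, labels, alpha: float = 0.05) -> RocResult:
    """AUC with a DeLong asymptotic-normal CI (clipped to [0, 1]) and the
    empirical ROC curve from (0,0) to (1,1)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAucError("both classes must be present")
    auc, v10, v01 = _structural_components(scores, labels)
    var = v10.var(ddof=1) / n_pos + v01.var(ddof=1) / n_neg
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.clip([auc - z * se, auc + z * se], 0.0, 1.0)

    # empirical curve: sweep unique thresholds, highest first
    order = np.argsort(-scores, kind="mergesort")
    s_sorted, l_sorted = scores[order], labels[order]
    tps = np.cumsum(l_sorted == 1)
    fps = np.cumsum(l_sorted == 0)
    keep = np.r_[np.diff(s_sorted) != 0, True]  # last point of each tie block
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    curve = np.column_stack([fpr, tpr])
    return RocResult(auc=float(auc), ci95=(float(lo), float(hi)),
                     n_pos=n_pos, n_neg=n_neg, curve=curve, se=se)


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p: float


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Two-sided DeLong test for two correlated AUCs on paired scores."""
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must have identical shape")
    auc_a, v10a, v01a = _structural_components(scores_a, labels)
    auc_b, v10b, v01b = _structural_components(scores_b, labels)
    m, n = v10a.size, v01a.size
    if m == 0 or n == 0:
        raise UndefinedAucError("both classes must be present")

    def cov(x, y):
        return np.cov(x, y, ddof=1)[0, 1] if x.size > 1 else 0.0

    var_a = v10a.var(ddof=1) / m + v01a.var(ddof=1) / n
    var_b = v10b.var(ddof=1) / m + v01b.var(ddof=1) / n
    cov_ab = cov(v10a, v10b) / m + cov(v01a, v01b) / n
    var_diff = var_a + var_b - 2 * cov_ab
    if var_diff <= 0:
        if np.isclose(auc_a, auc_b):
            return DeLongResult(auc_a, auc_b, var_a, var_b, cov_ab, z=0.0, p=1.0)
        raise DegenerateVarianceError("zero variance of the AUC difference with unequal AUCs")
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, var_a, var_b, cov_ab, z=float(z), p=p)


# ---------------------------------------------------------------------------
# threshold metrics


@dataclass
class MetricReport:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    accuracy: float
    ci: dict = field(default_factory=dict)  # name -> (lo, hi)
    counts: dict = field(default_factory=dict)


def threshold_metrics(scores, labels, threshold: float, alpha: float = 0.05) -> MetricReport:
    """Classification metrics at ``score >= threshold -> poor`` with Wilson
    score 95% CIs.  PPV/NPV with an empty predicted class are reported as
    None with a warning."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())

    def ratio(num, den):
        return num / den if den > 0 else None

    def wilson(num, den):
        if den == 0:
            return (np.nan, np.nan)
        lo, hi = proportion_confint(num, den, alpha=alpha, method="wilson")
        return (float(lo), float(hi))

    sens, spec = ratio(tp, tp + fn), ratio(tn, tn + fp)
    ppv, npv = ratio(tp, tp + fp), ratio(tn, tn + fn)
    if ppv is None:
        warnings.warn("no predicted positives: PPV undefined (NA)")
    if npv is None:
        warnings.warn("no predicted negatives: NPV undefined (NA)")
    n = tp + fp + fn + tn
    return MetricReport(
        threshold=float(threshold),
        sensitivity=sens if sens is not None else np.nan,
        specificity=spec if spec is not None else np.nan,
        ppv=ppv,
        npv=npv,
        accuracy=(tp + tn) / n,
        ci={
            "sensitivity": wilson(tp, tp + fn),
            "specificity": wilson(tn, tn + fp),
            "ppv": wilson(tp, tp + fp),
            "npv": wilson(tn, tn + fn),
            "accuracy": wilson(tp + tn, n),
        },
        counts={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct scores
    (plus one below the minimum and one above the maximum); ties in J are
    broken toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise UndefinedAucError("both classes must be present")
    uniq = np.unique(scores)
    candidates = np.r_[uniq[0] - 1.0, (uniq[:-1] + uniq[1:]) / 2.0, uniq[-1] + 1.0]
    n_pos, n_neg = (labels == 1).sum(), (labels == 0).sum()
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = scores >= t
        j = (pred & (labels == 1)).sum() / n_pos + (~pred & (labels == 0)).sum() / n_neg - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


# ---------------------------------------------------------------------------
# multivariate logistic regression


def _clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sex_male": [1 if r.sex == "male" else 0 for r in records],
            "age": [r.age for r in records],
            "cea_positive": [1 if r.cea == "positive" else 0 for r in records],
            "cT_T3": [1 if r.cT == "T3" else 0 for r in records],
            "cT_T4": [1 if r.cT == "T4" else 0 for r in records],
            "cN_N1": [1 if r.cN == "N1" else 0 for r in records],
            "cN_N2": [1 if r.cN == "N2" else 0 for r in records],
        }
    )


def multivariate_logistic(
    model_outputs: dict[str, np.ndarray],
    clinical: list[ClinicalRecord] | None,
    labels: np.ndarray,
    use_scores: bool = False,
) -> pd.DataFrame:
    """Odds ratios for each model output adjusted for the other predictors.

    ``model_outputs`` maps model name -> binary prediction (default) or
    continuous score (``use_scores=True``).  Clinical covariates (sex, age,
    CEA, cT, cN dummies) enter alongside the model columns.  Returns a
    DataFrame with OR, Wald 95% CI and p per predictor.  Perfect
    separation triggers an L2-penalized refit, flagged in the
    ``penalized`` column; duplicated (rank-deficient) predictor columns
    raise a warning.
    """
    import statsmodels.api as sm

    labels = np.asarray(labels).astype(int)
    cols = {}
    for name, out in model_outputs.items():
        out = np.asarray(out, dtype=np.float64)
        cols[name] = out if use_scores else (out > 0.5).astype(float) if out.dtype.kind == "f" and not set(np.unique(out)) <= {0.0, 1.0} else out
    X = pd.DataFrame(cols)
    if clinical is not None:
        X = pd.concat([X, _clinical_frame(clinical)], axis=1)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        warnings.warn("design matrix is rank deficient (duplicated/collinear predictors)")

    Xc = sm.add_constant(X, has_constant="add")
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(labels, Xc).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 20):
                raise np.linalg.LinAlgError("suspect separation")
        except Exception:
            penalized = True
            fit = sm.Logit(labels, Xc).fit_regularized(disp=0, alpha=1.0, L1_wt=0.0, maxiter=500)

    params = pd.Series(np.asarray(fit.params).ravel(), index=Xc.columns)
    try:
        bse = pd.Series(np.asarray(fit.bse).ravel(), index=Xc.columns)
    except Exception:
        bse = pd.Series(np.nan, index=Xc.columns)
    z = stats.norm.ppf(0.975)
    rows = []
    for name in X.columns:
        beta, se = params[name], bse[name]
        rows.append(
            {
                "predictor": name,
                "odds_ratio": float(np.exp(beta)),
                "ci_lo": float(np.exp(beta - z * se)) if np.isfinite(se) else np.nan,
                "ci_hi": float(np.exp(beta + z * se)) if np.isfinite(se) else np.nan,
                "p": float(2 * stats.norm.sf(abs(beta / se))) if np.isfinite(se) and se > 0 else np.nan,
                "penalized": penalized,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort comparison


def cohort_compare(
    records_a: list[ClinicalRecord],
    records_b: list[ClinicalRecord],
    yates: bool = False,
) -> dict[str, float]:
    """Per-variable p-values comparing two cohorts.

    Age uses the two-sided Mann-Whitney rank-sum test (tie-corrected
    normal approximation); categorical variables use Pearson chi-square
    without continuity correction by default.  A table with a zero
    expected cell yields NaN with a warning.
    """
    if len(records_a) < 2 or len(records_b) < 2:
        raise ValueError("need at least 2 records per cohort")
    out: dict[str, float] = {}
    age_a = [r.age for r in records_a]
    age_b = [r.age for r in records_b]
    out["age"] = float(
        stats.mannwhitneyu(age_a, age_b, alternative="two-sided", method="asymptotic").pvalue
    )

    def chi2(getter, categories):
        table = np.array(
            [
                [sum(1 for r in recs if getter(r) == c) for c in categories]
                for recs in (records_a, records_b)
            ],
            dtype=float,
        )
        table = table[:, table.sum(axis=0) > 0]  # drop empty categories
        if table.shape[1] < 2:
            warnings.warn("chi-square undefined: fewer than 2 observed categories")
            return np.nan
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        if (expected == 0).any():
            warnings.warn("chi-square undefined: zero expected cell count")
            return np.nan
        res = stats.chi2_contingency(table, correction=yates)
        return float(res.pvalue)

    out["sex"] = chi2(lambda r: r.sex, ("male", "female"))
    out["cea"] = chi2(lambda r: r.cea, ("positive", "negative"))
    out["cT"] = chi2(lambda r: r.cT, ("T2", "T3", "T4"))
    out["cN"] = chi2(lambda r: r.cN, ("N0", "N1", "N2"))
    out["response"] = chi2(lambda r: r.response, (0, 1))
    return out


# ---------------------------------------------------------------------------
# report assembly


def evaluate_models(
    scores_by_model: dict[str, np.ndarray],
    labels: np.ndarray,
    thresholds: dict[str, float] | None = None,
) -> dict:
    """Per-model AUC + threshold metrics and the pairwise DeLong p matrix.

    ``thresholds`` maps model -> frozen operating point (e.g. Youden's J on
    the training cohort); when absent the Youden threshold on the supplied
    data is used.  The DeLong matrix diagonal is 1 by convention.
    """
    labels = np.asarray(labels).astype(int)
    names = list(scores_by_model)
    report: dict = {"models": {}, "delong": {}}
    for name in names:
        s = np.asarray(scores_by_model[name], dtype=np.float64)
        roc = roc_auc(s, labels)
        thr = (thresholds or {}).get(name)
        if thr is None:
            thr = youden_threshold(s, labels)
        metrics = threshold_metrics(s, labels, thr)
        report["models"][name] = {"roc": roc, "metrics": metrics}
    for a in names:
        report["delong"][a] = {}
        for b in names:
            if a == b:
                report["delong"][a][b] = 1.0
            else:
                report["delong"][a][b] = delong_test(
                    scores_by_model[a], scores_by_model[b], labels
                ).p
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten an :func:`evaluate_models` report into a Table-2-style frame."""
    rows = []
    for name, entry in report["models"].items():
        roc: RocResult = entry["roc"]
        m: MetricReport = entry["metrics"]
        def fmt(v, ci):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return "NA"
            return f"{100 * v:.1f}% ({100 * ci[0]:.1f}-{100 * ci[1]:.1f}%)"
        rows.append(
            {
                "model": name,
                "AUC": f"{roc.auc:.3f} ({roc.ci95[0]:.3f}-{roc.ci95[1]:.3f})",
                "Accuracy": fmt(m.accuracy, m.ci["accuracy"]),
                "Sensitivity": fmt(m.sensitivity, m.ci["sensitivity"]),
                "Specificity": fmt(m.specificity, m.ci["specificity"]),
                "PPV": fmt(m.ppv, m.ci["ppv"]),
                "NPV": fmt(m.npv, m.ci["npv"]),
            }
        )
    return pd.DataFrame(rows)
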