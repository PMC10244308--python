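"""Statistical evaluation: bootstrap ROC with Youden thresholds, logistic fits.

Patch level: the distribution of ROC curves is obtained by repeatedly drawing
``n_per_group`` patches (default 128) from each of the positive
(future-lesion) and negative (normal) score pools, computing an empirical ROC
and its Youden operating point per replicate (default 10 replicates), and
summarising each metric with a 95% percentile interval over replicates.

Examination level: a maximum-likelihood logistic regression of future-lesion
presence on the examination-level score with a scanner-era indicator as
covariate; the score coefficient is tested with a Wald test at alpha = 0.05.
A threshold sweep over T_exam in 0.1..0.9 reports sensitivity, specificity,
PPV and NPV, optionally restratified by the malignancy-style grade grouping
(grades 1-2 vs 3-5).

Conventions (deliberate, deterministic): a sample is called positive iff its
score is strictly greater than the threshold; candidate Youden thresholds are
midpoints between adjacent distinct scores (plus sentinels outside the score
range), with ties broken toward the higher (more specific) threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

__all__ = [
    "RocResult",
    "BootstrapSummary",
    "LogisticFit",
    "roc_curve",
    "youden_threshold",
    "bootstrap_roc",
    "fit_exam_logistic",
    "threshold_sweep",
    "malignancy_stratified_eval",
]

DEFAULT_ALPHA = 0.05
DEFAULT_T_EXAM_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    fpr_at_threshold: float
    n_pos: int
    n_neg: int


@dataclass
class BootstrapSummary:
    replicates: list[RocResult]
    ci: dict[str, tuple[float, float]]
    n_per_group: int
    n_replicates: int
    sampled_with_replacement: bool = False


@dataclass
class LogisticFit:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    wald_z: dict[str, float]
    p_values: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    converged: bool
    alpha: float = DEFAULT_ALPHA
    diagnostic: str | None = None

    @property
    def score_significant(self) -> bool:
        return self.converged and self.p_values["exam_score"] < self.alpha


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC over all distinct score thresholds (positive iff score > t).

    AUC is the trapezoidal area, which with tied scores equals the
    Mann-Whitney statistic (ties take half credit). The Youden operating
    point is attached (see :func:`youden_threshold`).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    _check_two_classes(labels)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)

    # step ROC: sweep thresholds from high to low over distinct scores
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(1 - l_sorted)
    boundary = np.r_[np.nonzero(distinct)[0][1:] - 1, s_sorted.size - 1]
    tpr = np.r_[0.0, tp[boundary] / n_pos]
    fpr = np.r_[0.0, fp[boundary] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))

    thr, sens, spec, fpr_at = _youden_search(scores, labels, n_pos, n_neg)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                     youden_threshold=thr, sensitivity=sens, specificity=spec,
                     fpr_at_threshold=fpr_at, n_pos=n_pos, n_neg=n_neg)


def _youden_search(scores, labels, n_pos, n_neg):
    distinct = np.unique(scores)
    if distinct.size == 1:
        candidates = distinct  # score > t classifies nothing positive; J = 0
    else:
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        gap = distinct[1] - distinct[0]
        candidates = np.r_[distinct[0] - gap, mids, distinct[-1] + gap]
    best = None
    for t in candidates:  # ascending; >= keeps the higher threshold on ties
        pred = scores > t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        sens = tp / n_pos
        spec = 1.0 - fp / n_neg
        j = sens + spec - 1.0
        if best is None or j >= best[0] - 1e-12:
            best = (j, float(t), sens, spec, fp / n_neg)
    return best[1], best[2], best[3], best[4]


def youden_threshold(roc: RocResult) -> tuple[float, float, float, float]:
    """(threshold, sensitivity, specificity, fpr) at the Youden optimum.

    The threshold maximizes J = sensitivity + specificity - 1 over midpoints
    between adjacent distinct scores; ties resolve toward the higher (more
    specific) threshold. Metrics are recomputed at the returned threshold.
    """
    return (roc.youden_threshold, roc.sensitivity, roc.specificity,
            roc.fpr_at_threshold)


def bootstrap_roc(pos_scores, neg_scores, n_per_group: int = 128,
                  n_replicates: int = 10, seed: int = 0,
                  ci_level: float = 0.95) -> BootstrapSummary:
    """Distribution of ROC curves over random patch subsamples.

    Each replicate draws ``n_per_group`` scores from each cohort pool without
    replacement (falling back to sampling with replacement when a pool is
    smaller than ``n_per_group``), computes a ROC and its Youden operating
    point, and the summary reports percentile confidence intervals over the
    replicates for AUC, sensitivity, specificity and FPR.
    """
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score pools must be non-empty")
    rng = np.random.default_rng(seed)
    with_replacement = pos.size < n_per_group or neg.size < n_per_group
    reps = []
    for _ in range(n_replicates):
        ps = rng.choice(pos, n_per_group, replace=pos.size < n_per_group)
        ns = rng.choice(neg, n_per_group, replace=neg.size < n_per_group)
        scores = np.r_[ps, ns]
        labels = np.r_[np.ones(n_per_group, int), np.zeros(n_per_group, int)]
        reps.append(roc_curve(scores, labels))
    lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    ci = {}
    for name in ("auc", "sensitivity", "specificity", "fpr_at_threshold",
                 "youden_threshold"):
        vals = np.array([getattr(r, name) for r in reps])
        ci[name] = (float(np.percentile(vals, lo_q)),
                    float(np.percentile(vals, hi_q)))
    return BootstrapSummary(replicates=reps, ci=ci, n_per_group=n_per_group,
                            n_replicates=n_replicates,
                            sampled_with_replacement=with_replacement)


_COEF_NAMES = ("intercept", "exam_score", "scanner_indicator")


def fit_exam_logistic(exam_scores, labels, scanner_indicator,
                      alpha: float = DEFAULT_ALPHA) -> LogisticFit:
    """Logistic regression of future-lesion presence on exam score + scanner.

    Wald z = coefficient / SE with a two-sided normal p-value; the score
    coefficient's significance is judged at ``alpha``. Complete or
    quasi-complete separation is flagged as non-convergent with a diagnostic
    rather than reporting unstable coefficients.
    """
    x = np.asarray(exam_scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    s = np.asarray(scanner_indicator, dtype=np.float64)
    if np.isnan(x).any() or np.isnan(s).any():
        raise ValueError("missing values in predictors")
    if len(np.unique(y)) < 2:
        raise ValueError("need both outcome classes to fit the model")
    if np.ptp(x) == 0:
        raise ValueError("exam_score has zero variance: coefficient not identifiable")

    X = np.column_stack([np.ones_like(x), x, s])
    import warnings

    diagnostic = None
    converged = True
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation warnings are handled explicitly via the checks below
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="newton")
            except Exception:
                # singular Hessian under (quasi-)separation: retry with a
                # gradient method, then let the stability checks judge it
                res = sm.Logit(y, X).fit(disp=0, maxiter=500, method="bfgs")
        params = res.params
        bse = res.bse
        converged = bool(res.mle_retvals.get("converged", True))
        # quasi-separation shows up as exploding coefficients / SEs
        if not np.isfinite(bse).all() or np.abs(params).max() > 1e3 \
                or np.nanmax(bse) > 1e3:
            converged = False
            diagnostic = "separation suspected: unstable coefficients or standard errors"
    except Exception as exc:  # PerfectSeparationError and friends
        return LogisticFit(
            coefficients={}, standard_errors={}, wald_z={}, p_values={},
            conf_int={}, converged=False, alpha=alpha,
            diagnostic=f"non-convergent fit: {exc}")
    if not converged and diagnostic is None:
        diagnostic = "maximum-likelihood fit did not converge"

    from scipy.stats import norm
    coefs = dict(zip(_COEF_NAMES, map(float, params)))
    ses = dict(zip(_COEF_NAMES, map(float, bse)))
    z = {k: coefs[k] / ses[k] if ses[k] > 0 else np.inf for k in _COEF_NAMES}
    p = {k: float(2 * norm.sf(abs(z[k]))) for k in _COEF_NAMES}
    zq = norm.ppf(0.975)
    ci = {k: (coefs[k] - zq * ses[k], coefs[k] + zq * ses[k]) for k in _COEF_NAMES}
    return LogisticFit(coefficients=coefs, standard_errors=ses, wald_z=z,
                       p_values=p, conf_int=ci, converged=converged,
                       alpha=alpha, diagnostic=diagnostic)


def neg_log_likelihood(params, X, y):
    """Logistic negative log-likelihood (exposed for independent cross-checks)."""
    eta = X @ params
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


def fit_logistic_reference(X, y, x0=None):
    """Independent fit via a general-purpose numerical minimizer (oracle path)."""
    if x0 is None:
        x0 = np.zeros(X.shape[1])
    res = optimize.minimize(neg_log_likelihood, x0, args=(X, y),
                            method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    return res.x


def threshold_sweep(exam_scores, labels,
                    thresholds=DEFAULT_T_EXAM_GRID) -> pd.DataFrame:
    """Sensitivity/specificity/PPV/NPV over T_exam (positive iff score > T)."""
    x = np.asarray(exam_scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    rows = []
    for t in thresholds:
        pred = x > t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        rows.append({
            "t_exam": float(t), "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "ppv": tp / (tp + fp) if tp + fp else np.nan,
            "npv": tn / (tn + fn) if tn + fn else np.nan,
        })
    return pd.DataFrame(rows)


def malignancy_stratified_eval(exam_scores, final_grades,
                               thresholds=DEFAULT_T_EXAM_GRID
                               ) -> dict[str, pd.DataFrame]:
    """Threshold sweeps under the two grade groupings.

    ``any_lesion``: positives are grade >= 2 (every lesion counts).
    ``grade_3plus``: positives are grades 3-5, negatives grades 1-2 — the
    malignancy-oriented regrouping. An empty stratum yields an all-NA table.
    """
    x = np.asarray(exam_scores, dtype=np.float64)
    g = np.asarray(final_grades).astype(int)
    out = {}
    for name, labels in (("any_lesion", (g >= 2).astype(int)),
                         ("grade_3plus", (g >= 3).astype(int))):
        if len(np.unique(labels)) < 2:
            na = threshold_na_table(thresholds)
            out[name] = na
        else:
            out[name] = threshold_sweep(x, labels, thresholds)
    return out


def threshold_na_table(thresholds=DEFAULT_T_EXAM_GRID) -> pd.DataFrame:
    rows = [{"t_exam": float(t), "tp": np.nan, "fp": np.nan, "tn": np.nan,
             "fn": np.nan, "sensitivity": np.nan, "specificity": np.nan,
             "ppv": np.nan, "npv": np.nan} for t in thresholds]
    return pd.DataFrame(rows)
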