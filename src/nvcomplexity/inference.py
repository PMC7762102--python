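"""Group inference and classification on the cohort feature table.

Implements the statistical battery applied to the 17 complexity features:
per-group percentile-bootstrap 95% confidence-interval filtering of subject
values, unpaired pooled-variance t-tests with Benjamini-Hochberg FDR
adjustment and Cohen's d, a GLM (ordinary-least-squares) classifier of
disease label per feature family evaluated by leave-one-out cross-validation,
ROC/AUC analysis of the out-of-sample scores, and DeLong's paired test for
comparing correlated AUCs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FAMILIES, FEATURE_NAMES

__all__ = [
    "TestResult",
    "ROCResult",
    "bh_adjust",
    "bootstrap_ci_filter",
    "apply_ci_filter",
    "ttests_fdr",
    "glm_loocv_classify",
    "roc_analysis",
    "youden_threshold",
    "compare_auc",
]

log = logging.getLogger(__name__)


@dataclass
class TestResult:
    metric: str
    t: float
    df: int
    p: float
    q: float
    cohen_d: float
    n_ad: int
    n_hc: int


@dataclass
class ROCResult:
    """Out-of-sample classification result for one feature family x phase."""

    family: str
    phase: str
    subject_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    betas: dict[str, float] = field(default_factory=dict)
    threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def bootstrap_ci_filter(
    values,
    n_boot: int = 1000,
    ci: float = 95.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Bootstrap 95% CI of a group's value distribution; flag values outside.

    Each of ``n_boot`` resamples contributes a normal-theory interval
    ``mean_b +- z * SD_b`` for the distribution's central ``ci`` mass; the
    bounds are averaged over resamples.  The moments-based form (rather
    than within-sample percentiles) lets the interval extend beyond the
    observed range, so typical samples lose no values at all and only
    genuine outliers are excluded.  Returns ``(retained_mask,
    (lower, upper))``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("group too small for a bootstrap CI (n < 3)")
    if rng is None:
        rng = np.random.default_rng(0)
    z = stats.norm.ppf(0.5 + ci / 200.0)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    resamples = values[idx]
    means = resamples.mean(axis=1)
    sds = resamples.std(axis=1, ddof=1)
    lower = float((means - z * sds).mean())
    upper = float((means + z * sds).mean())
    tol = 1e-9 * max(1.0, abs(lower), abs(upper))
    mask = (values >= lower - tol) & (values <= upper + tol)
    return mask, (lower, upper)


def apply_ci_filter(
    table: pd.DataFrame,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Invalidate per-metric subject values outside their group's bootstrap CI.

    Operates per phase x feature x group; individual values are excluded
    (validity flag cleared), not whole subjects, so each metric keeps its own
    degrees of freedom downstream.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    table = table.copy()
    for phase in table["phase"].unique():
        for feat in FEATURE_NAMES:
            for group in (0, 1):
                sel = (
                    (table["phase"] == phase)
                    & (table["group"] == group)
                    & table[f"valid_{feat}"]
                    & table[feat].notna()
                )
                vals = table.loc[sel, feat].to_numpy()
                if vals.size < 3:
                    continue
                mask, _ = bootstrap_ci_filter(vals, n_boot=n_boot, rng=rng)
                excluded = sel[sel].index[~mask]
                table.loc[excluded, f"valid_{feat}"] = False
    return table


def _cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def ttests_fdr(table: pd.DataFrame, phase: str, alpha: float = 0.05) -> pd.DataFrame:
    """Unpaired pooled-variance t-tests (AD vs HC) per metric with BH-FDR.

    The FDR family is all metrics within the given phase.  Degrees of
    freedom reflect per-metric exclusions from the validity/CI filters.
    """
    sub = table[table["phase"] == phase]
    results: list[TestResult] = []
    p_list = []
    for feat in FEATURE_NAMES:
        valid = sub[f"valid_{feat}"] & sub[feat].notna()
        ad = sub.loc[valid & (sub["group"] == 1), feat].to_numpy()
        hc = sub.loc[valid & (sub["group"] == 0), feat].to_numpy()
        if ad.size < 2 or hc.size < 2:
            log.warning("metric %s skipped in phase %s: group too small", feat, phase)
            continue
        if ad.std(ddof=1) == 0 and hc.std(ddof=1) == 0 and ad.mean() == hc.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(ad, hc, equal_var=True)
        results.append(
            TestResult(
                metric=feat,
                t=float(t),
                df=ad.size + hc.size - 2,
                p=float(p),
                q=np.nan,
                cohen_d=_cohen_d(ad, hc),
                n_ad=ad.size,
                n_hc=hc.size,
            )
        )
        p_list.append(float(p))
    if results:
        q = bh_adjust(p_list)
        for res, qv in zip(results, q):
            res.q = float(qv)
    frame = pd.DataFrame([vars(r) for r in results])
    frame.attrs["phase"] = phase
    frame.attrs["alpha"] = alpha
    return frame


def _loocv_scores(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Out-of-sample OLS predictions, one held-out row at a time."""
    n = y.size
    scores = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        beta, _, rank, _ = np.linalg.lstsq(design[keep], y[keep], rcond=None)
        if rank < design.shape[1]:
            warnings.warn("rank-deficient design; pseudo-inverse fit", stacklevel=3)
        scores[i] = design[i] @ beta
    return scores


def glm_loocv_classify(
    table: pd.DataFrame,
    family: str,
    phase: str,
    threshold: float | None = None,
) -> ROCResult:
    """Leave-one-out GLM classification of disease label from one family.

    For each held-out subject an ordinary-least-squares linear regression of
    the label (AD=1, HC=0) on the family's features (intercept included) is
    fitted on the remaining subjects and used to score the held-out one.  A
    full-sample fit supplies the reported beta weights.  Subjects with any
    invalid feature in the family are dropped for that family.
    """
    feats = list(FAMILIES[family])
    sub = table[table["phase"] == phase]
    ok = np.ones(len(sub), dtype=bool)
    for feat in feats:
        ok &= (sub[f"valid_{feat}"] & sub[feat].notna()).to_numpy()
    dropped = (~ok).sum()
    if dropped:
        log.info("family %s phase %s: dropped %d subjects with invalid features",
                 family, phase, dropped)
    sub = sub[ok]
    y = sub["group"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both groups must be present")
    x = sub[feats].to_numpy(dtype=float)
    if y.size <= x.shape[1] + 1:
        raise ValueError(
            f"too few subjects ({y.size}) for {x.shape[1]} features"
        )
    design = np.column_stack([np.ones(y.size), x])
    scores = _loocv_scores(design, y)
    beta_full, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    betas = {"intercept": float(beta_full[0])}
    betas.update({f: float(b) for f, b in zip(feats, beta_full[1:])})
    result = roc_analysis(scores, y, threshold=threshold)
    result.family = family
    result.phase = phase
    result.subject_ids = sub["subject_id"].tolist()
    result.betas = betas
    return result


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney U) formulation with midranks for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_analysis(
    scores, labels, threshold: float | None = None
) -> ROCResult:
    """ROC curve by threshold sweep plus rank-based AUC.

    The step curve runs from (0,0) to (1,1) over the unique scores in
    descending order (score >= threshold => predicted AD).  The reported AUC
    uses the Mann-Whitney formulation, which equals the trapezoidal area of
    the sweep.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for k, thr in enumerate(thresholds):
        pred = scores >= thr
        tpr[k] = (pred & (labels == 1)).sum() / n_pos
        fpr[k] = (pred & (labels == 0)).sum() / n_neg
    auc = _auc_mann_whitney(scores, labels)
    result = ROCResult(
        family="", phase="", subject_ids=[], scores=scores, labels=labels,
        fpr=fpr, tpr=tpr, auc=auc,
    )
    if threshold is not None:
        pred = scores >= threshold
        result.threshold = float(threshold)
        result.sensitivity = float((pred & (labels == 1)).sum() / n_pos)
        result.specificity = float((~pred & (labels == 0)).sum() / n_neg)
    return result


def sweep_auc(result: ROCResult) -> float:
    """Trapezoidal area under the threshold-sweep ROC curve."""
    return float(np.trapezoid(result.tpr, result.fpr))


def youden_threshold(result: ROCResult) -> float:
    """Score threshold maximizing sensitivity + specificity - 1.

    A convenience helper: operating thresholds are otherwise inputs chosen
    by the user for the desired sensitivity/specificity compromise, not
    optimized by default.
    """
    j = result.tpr - result.fpr
    thresholds = np.concatenate(([np.inf], np.unique(result.scores)[::-1]))
    return float(thresholds[np.argmax(j)])


def _delong_structural_components(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per-positive placement values
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-negative
    auc = v10.mean()
    return auc, v10, v01


def compare_auc(result_a: ROCResult, result_b: ROCResult) -> tuple[float, float]:
    """DeLong paired test for two correlated ROC curves.

    Both score vectors must come from the same subjects in the same order.
    Returns ``(z, p)`` two-sided; the sign of z follows ``AUC_a - AUC_b``.
    """
    if result_a.subject_ids and result_b.subject_ids:
        if result_a.subject_ids != result_b.subject_ids:
            raise ValueError("unpaired inputs: subject sets differ")
    elif not np.array_equal(result_a.labels, result_b.labels):
        raise ValueError("unpaired inputs: labels differ")
    labels = result_a.labels
    auc_a, v10_a, v01_a = _delong_structural_components(result_a.scores, labels)
    auc_b, v10_b, v01_b = _delong_structural_components(result_b.scores, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0 or diff == 0:
        z = 0.0
    else:
        z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z)) if z != 0 else 1.0
    return float(z), float(p)
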