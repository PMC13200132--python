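"""Agreement and paired-comparison statistics for the study layer.

Paired tests (Wilcoxon signed-rank, paired t) compare metric values between
the two reconstructions; rater agreement uses Cohen's kappa and Kendall's
tau-b/tau-c on ordinal Likert ratings; method agreement across the three
edge detectors uses the within-participant coefficient of variation and a
two-way mixed-effects intraclass correlation (consistency and absolute
agreement, single and average measures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import EdgeFeatureResult

__all__ = [
    "ICCResult",
    "wilcoxon_signed_rank",
    "paired_t",
    "cohen_kappa",
    "kendall_tau",
    "within_participant_cv",
    "icc_two_way_mixed",
    "detector_agreement_report",
]


@dataclass
class ICCResult:
    """Two-way mixed-effects ICC point estimates and the mean squares behind
    them (rows = subjects, columns = raters/methods, no interaction term)."""

    icc_single_consistency: float
    icc_avg_consistency: float
    icc_single_agreement: float
    icc_avg_agreement: float
    msr: float
    msc: float
    mse: float
    n: int
    k: int


def wilcoxon_signed_rank(pairs) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on (a, b) pairs.

    Zero differences are dropped (classic Wilcoxon convention); all-zero
    input returns p = 1 with a warning. The exact null distribution is used
    for small samples without ties, the tie-corrected normal approximation
    otherwise (scipy's ``method='auto'``).
    """
    a, b = _split_pairs(pairs)
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def paired_t(pairs) -> tuple[float, float]:
    """Two-sided paired t-test (n-1 df).

    Zero-variance differences are degenerate: a constant nonzero difference
    returns a signed infinite t with p = 0 (and a warning); identically zero
    differences return t = 0, p = 1.
    """
    a, b = _split_pairs(pairs)
    if a.size < 3:
        raise ValueError("paired t-test requires n >= 3")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if d[0] == 0:
            warnings.warn("all differences zero; t = 0, p = 1")
            return 0.0, 1.0
        warnings.warn("constant nonzero differences; t = +/-inf, p = 0")
        return float(np.sign(d[0]) * np.inf), 0.0
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def cohen_kappa(r1, r2) -> float:
    """Unweighted Cohen's kappa between two raters' ordinal labels.

    Returns NaN (with a warning) when both raters use a single shared
    category, where chance agreement is 1 and kappa is undefined.
    """
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape:
        raise ValueError("rating vectors must have equal length")
    if np.unique(np.concatenate([r1, r2])).size < 2:
        warnings.warn("single shared category: kappa undefined")
        return float("nan")
    from sklearn.metrics import cohen_kappa_score

    return float(cohen_kappa_score(r1, r2))


def kendall_tau(r1, r2, variant: str = "b") -> float:
    """Kendall's tau-b or tau-c rank correlation.

    tau-b applies the geometric-mean tie correction; tau-c the rectangular
    (m-category) correction. Constant input on either side is a NaN sentinel.
    """
    if variant not in ("b", "c"):
        raise ValueError("variant must be 'b' or 'c'")
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.ptp(r1) == 0 or np.ptp(r2) == 0:
        warnings.warn("constant ratings: tau undefined")
        return float("nan")
    res = sps.kendalltau(r1, r2, variant=variant)
    return float(res.statistic)


def within_participant_cv(table) -> tuple[np.ndarray, float]:
    """Within-participant coefficient of variation, in percent.

    Per subject (row): SD across the k columns divided by the row mean,
    x100. The summary is the mean of the per-subject CVs. Subjects with a
    non-positive mean are excluded with a warning.
    """
    x = _as_table(table, min_k=2, min_n=1)
    means = x.mean(axis=1)
    ok = means > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} subject(s) with non-positive mean excluded from CV")
    sds = x.std(axis=1, ddof=1)
    cvs = np.full(x.shape[0], np.nan)
    cvs[ok] = sds[ok] / means[ok] * 100.0
    return cvs, float(np.nanmean(cvs)) if ok.any() else float("nan")


def icc_two_way_mixed(table) -> ICCResult:
    """Two-way mixed-effects ICC (Shrout-Fleiss / Koo conventions).

    From the two-way ANOVA mean squares of a complete n x k table
    (MSR rows/subjects, MSC columns/raters, MSE residual):

    * single consistency  ICC(3,1) = (MSR-MSE) / (MSR+(k-1)MSE)
    * average consistency ICC(3,k) = (MSR-MSE) / MSR
    * single agreement    ICC(2,1)-form = (MSR-MSE) /
      (MSR+(k-1)MSE + k(MSC-MSE)/n)
    * average agreement   = (MSR-MSE) / (MSR + (MSC-MSE)/n)

    MSR = 0 (no subject variance) yields NaN sentinels with a warning.
    """
    x = _as_table(table, min_k=2, min_n=3)
    n, k = x.shape
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - gm) ** 2) / (n - 1)
    msc = n * np.sum((col_means - gm) ** 2) / (k - 1)
    mse = np.sum((x - row_means[:, None] - col_means[None, :] + gm) ** 2) / (
        (n - 1) * (k - 1)
    )
    if msr == 0:
        warnings.warn("no between-subject variance: ICC undefined")
        nan = float("nan")
        return ICCResult(nan, nan, nan, nan, msr, msc, mse, n, k)
    single_c = (msr - mse) / (msr + (k - 1) * mse)
    avg_c = (msr - mse) / msr
    single_a = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    avg_a = (msr - mse) / (msr + (msc - mse) / n)
    return ICCResult(
        float(single_c), float(avg_c), float(single_a), float(avg_a),
        float(msr), float(msc), float(mse), n, k,
    )


def detector_agreement_report(features: dict[str, list[EdgeFeatureResult]]) -> pd.DataFrame:
    """Cross-detector variability/agreement per sharpness feature.

    ``features`` maps subject id -> list of EdgeFeatureResult (one per
    detector). Subjects lacking any detector are dropped with a warning.
    Returns one row per feature with the summary CV and the four ICC forms
    across detectors.
    """
    detectors = sorted(
        {r.detector for results in features.values() for r in results}
    )
    attr = {
        "steepness": "mean_steepness",
        "width": "mean_width_px",
        "contrast": "mean_contrast",
    }
    rows = []
    kept: dict[str, dict[str, EdgeFeatureResult]] = {}
    for sid, results in features.items():
        by_det = {r.detector: r for r in results if r.valid}
        if set(detectors) <= set(by_det):
            kept[sid] = by_det
        else:
            warnings.warn(f"subject {sid}: incomplete detector coverage, dropped")
    if len(kept) < 3:
        raise ValueError("need >= 3 subjects with complete detector coverage")
    for feat, a in attr.items():
        tab = np.array(
            [[getattr(kept[sid][d], a) for d in detectors] for sid in sorted(kept)]
        )
        _, cv = within_participant_cv(tab)
        icc = icc_two_way_mixed(tab)
        rows.append(
            {
                "feature": feat,
                "cv_percent": cv,
                "icc_single_consistency": icc.icc_single_consistency,
                "icc_avg_consistency": icc.icc_avg_consistency,
                "icc_single_agreement": icc.icc_single_agreement,
                "icc_avg_agreement": icc.icc_avg_agreement,
                "n_subjects": icc.n,
                "detectors": ",".join(detectors),
            }
        )
    return pd.DataFrame(rows)


def _split_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b) tuples")
    return arr[:, 0], arr[:, 1]


def _as_table(table, min_k: int, min_n: int) -> np.ndarray:
    x = np.asarray(
        table.values if isinstance(table, pd.DataFrame) else table, dtype=float
    )
    if x.ndim != 2:
        raise ValueError("rating table must be 2D (subjects x columns)")
    if np.isnan(x).any():
        raise ValueError("rating table must be complete (no missing cells)")
    n, k = x.shape
    if k < min_k or n < min_n:
        raise ValueError(f"table must be at least {min_n}x{min_k}, got {n}x{k}")
    return x
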