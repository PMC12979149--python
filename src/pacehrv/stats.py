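"""Cohort-level repeated-measures statistics for the pacing protocol.

The analysis mirrors the protocol's prespecified plan: Friedman's
non-parametric ANOVA across periods A–D; two-sided Wilcoxon signed-rank
tests on the prespecified pacing contrasts (A vs B, C vs D) against a
Bonferroni threshold of alpha/2 = 0.025, with A vs C and B vs D reported
descriptively; Bland-Altman agreement (bias, SD of differences, relative
bias) with a first-minus-second orientation and limits of agreement
deliberately omitted — on 4-cycle windows their interpretation would be
unstable; second-order difference plots (SODP) of consecutive between-period
deltas; positive-delta frequencies; and Shapiro-Wilk-gated Spearman
correlation plus ICC(A,1)/Lin's CCC as secondary repeatability descriptors.

The cohort frame is a wide pandas DataFrame: one row per patient, columns a
two-level (metric, period) MultiIndex.  Missing periods (repeat rule failed)
are NaN; pairwise statistics use pairwise-complete cases, Friedman and SODP
use listwise-complete cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

PERIODS = ("A", "B", "C", "D")
#: prespecified pacing contrasts (Bonferroni-corrected)
PRESPECIFIED = (("A", "B"), ("C", "D"))
#: descriptive contrasts (baseline and post-pacing stability)
DESCRIPTIVE = (("A", "C"), ("B", "D"))
#: above this n the Wilcoxon p-value uses the normal approximation with
#: continuity correction instead of the exact null distribution
WILCOXON_EXACT_MAX_N = 25


@dataclass
class AgreementResult:
    """Bland-Altman agreement for one (metric, period-pair)."""

    pair: tuple[str, str]
    bias: float  # ms, mean of first - second
    sd_diff: float  # ms, sample SD (n-1) of the differences
    pct_bias: float  # %, 100 * bias / grand mean of the pooled pair
    n: int


@dataclass
class SODPRecord:
    """Consecutive between-period differences for one patient."""

    patient_id: str
    deltas: tuple[float, float, float]  # B-A, C-B, D-C
    points: tuple[tuple[float, float], tuple[float, float]]  # (d1,d2), (d2,d3)
    quadrants: tuple[str, str]


def _pair_vectors(
    frame: pd.DataFrame, metric: str, pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete vectors for (metric, first period), (metric, second)."""
    sub = frame[[(metric, pair[0]), (metric, pair[1])]].dropna()
    return sub[(metric, pair[0])].to_numpy(float), sub[(metric, pair[1])].to_numpy(float)


def bland_altman(
    frame: pd.DataFrame, metric: str, pair: tuple[str, str]
) -> AgreementResult:
    """Bland-Altman bias, SD of differences and relative bias for a pair.

    Differences are oriented first-listed period minus second, so a negative
    bias means higher values in the second (post-pacing) period.  Relative
    bias is the bias divided by the grand mean of the pooled pair.  Limits
    of agreement are intentionally not part of the result.
    """
    first, second = _pair_vectors(frame, metric, pair)
    if first.size < 2:
        raise ValueError(f"need >= 2 complete pairs for {metric} {pair}")
    diffs = first - second
    bias = float(np.mean(diffs))
    sd_diff = float(np.std(diffs, ddof=1))
    grand_mean = float(np.mean(np.concatenate([first, second])))
    pct = 100.0 * bias / grand_mean if grand_mean != 0 else float("nan")
    return AgreementResult(pair=pair, bias=bias, sd_diff=sd_diff, pct_bias=pct,
                           n=int(first.size))


def positive_delta_freq(
    frame: pd.DataFrame, metric: str, contrast: tuple[str, str]
) -> tuple[int, float]:
    """Count and percentage of patients whose metric increased after pacing.

    A positive delta is a strict increase (post - pre > 0); ties do not
    count.  The percentage is over complete pairs.
    """
    pre, post = _pair_vectors(frame, metric, contrast)
    if pre.size == 0:
        raise ValueError(f"no complete pairs for {metric} {contrast}")
    count = int(np.sum(post - pre > 0))
    return count, 100.0 * count / pre.size


def _quadrant(x: float, y: float) -> str:
    if x == 0 or y == 0:
        return "axis"
    return ("+" if x > 0 else "-") + ("+" if y > 0 else "-")


def sodp(frame: pd.DataFrame, metric: str) -> tuple[list[SODPRecord], dict, list[str]]:
    """Second-order difference plot series for every listwise-complete patient.

    For each patient: d1 = B-A, d2 = C-B, d3 = D-C; the plotted points are
    (d1, d2) and (d2, d3).  Returns the per-patient records, a cohort summary
    of quadrant fractions per point type, and the ids of skipped patients
    (missing periods).
    """
    records: list[SODPRecord] = []
    skipped: list[str] = []
    cols = [(metric, p) for p in PERIODS]
    for pid, row in frame[cols].iterrows():
        vals = row.to_numpy(float)
        if np.any(np.isnan(vals)):
            skipped.append(str(pid))
            continue
        a, b, c, d = vals
        d1, d2, d3 = b - a, c - b, d - c
        points = ((d1, d2), (d2, d3))
        records.append(SODPRecord(
            patient_id=str(pid),
            deltas=(d1, d2, d3),
            points=points,
            quadrants=(_quadrant(*points[0]), _quadrant(*points[1])),
        ))
    summary: dict = {}
    for which, idx in (("d1_d2", 0), ("d2_d3", 1)):
        counts: dict[str, int] = {}
        for rec in records:
            counts[rec.quadrants[idx]] = counts.get(rec.quadrants[idx], 0) + 1
        total = max(len(records), 1)
        summary[which] = {q: counts.get(q, 0) / total
                          for q in ("++", "+-", "-+", "--", "axis")}
    return records, summary, skipped


def wilcoxon_signed_rank(
    pre: np.ndarray, post: np.ndarray
) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Zero differences are dropped (classical convention).  The exact null
    distribution is used for n <= 25 non-zero pairs, the normal
    approximation with continuity correction above that.  All-tied data
    yields statistic 0 and p = 1 rather than an error.
    """
    d = np.asarray(post, float) - np.asarray(pre, float)
    d = d[~np.isnan(d)]
    nz = d[d != 0]
    if nz.size == 0:
        return {"statistic": 0.0, "p": 1.0, "n": 0, "method": "degenerate"}
    if nz.size <= WILCOXON_EXACT_MAX_N:
        res = sps.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                           method="exact")
        method = "exact"
    else:
        res = sps.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                           method="approx", correction=True)
        method = "normal-approx"
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "n": int(nz.size), "method": method}


def friedman_across_periods(frame: pd.DataFrame, metric: str) -> dict:
    """Friedman non-parametric ANOVA across A-D (listwise complete)."""
    cols = [(metric, p) for p in PERIODS]
    sub = frame[cols].dropna()
    n = int(len(sub))
    if n < 2:
        raise ValueError(f"need >= 2 complete patients for Friedman on {metric}")
    samples = [sub[c].to_numpy(float) for c in cols]
    if np.ptp(np.column_stack(samples), axis=1).max() == 0:
        # every patient identical across periods: no evidence of any effect
        return {"statistic": 0.0, "p": 1.0, "n": n}
    stat, p = sps.friedmanchisquare(*samples)
    return {"statistic": float(stat), "p": float(p), "n": n}


def contrast_tests(
    frame: pd.DataFrame, metric: str, alpha: float = 0.05, bonferroni_m: int = 2
) -> dict:
    """Friedman across A-D plus the per-contrast Wilcoxon tests.

    The prespecified pacing contrasts A-B and C-D are flagged significant
    when p < alpha / bonferroni_m (0.025 by default); A-C and B-D are
    reported descriptively, without a significance flag.
    """
    threshold = alpha / bonferroni_m
    report: dict = {
        "metric": metric,
        "bonferroni_threshold": threshold,
        "friedman": friedman_across_periods(frame, metric),
        "contrasts": {},
    }
    for pair in PRESPECIFIED + DESCRIPTIVE:
        pre, post = _pair_vectors(frame, metric, pair)
        res = wilcoxon_signed_rank(pre, post)
        res["prespecified"] = pair in PRESPECIFIED
        if pair in PRESPECIFIED:
            res["significant"] = res["p"] < threshold
        report["contrasts"]["%s-%s" % pair] = res
    return report


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # 1/n, per Lin's original definition
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return float("nan")
    return float(2.0 * cov / denom)


def icc_absolute_agreement(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single measure."""
    import pingouin as pg

    n = len(x)
    data = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["first", "second"], n),
        "score": np.concatenate([np.asarray(x, float), np.asarray(y, float)]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=data, targets="subject", raters="rater", ratings="score"
        )
    return float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])


def repeatability(
    frame: pd.DataFrame, metric: str, pair: tuple[str, str]
) -> dict:
    """Repeatability panel for one period pair.

    Shapiro-Wilk on the paired differences gates the interpretation:
    Spearman's rho is always computed and is the primary descriptor when
    normality is rejected.  ICC(A,1) and Lin's CCC are secondary absolute-
    agreement descriptors (both are unstable at 4-cycle window lengths and
    low between-subject variance).
    """
    x, y = _pair_vectors(frame, metric, pair)
    if x.size < 5:
        raise ValueError(f"need >= 5 complete pairs for repeatability on {metric} {pair}")
    d = x - y
    out: dict = {"metric": metric, "pair": "%s-%s" % pair, "n": int(x.size)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        out["shapiro_p"] = float(sps.shapiro(d).pvalue) if np.ptp(d) > 0 else 1.0
    out["normality_rejected"] = out["shapiro_p"] < 0.05
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        out["spearman_rho"] = None
        out["spearman_p"] = None
        out["spearman_missing_reason"] = "zero variance in a period vector"
    else:
        rho, p = sps.spearmanr(x, y)
        out["spearman_rho"] = float(rho)
        out["spearman_p"] = float(p)
    out["icc"] = icc_absolute_agreement(x, y)
    out["ccc"] = lin_ccc(x, y)
    return out
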