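"""Benchmark statistics of speed-accuracy tradeoff RT data.

Three qualitative signatures distinguish fast-guess-contaminated data
across speed-stress conditions:

1. mean error RT minus mean correct RT flips sign — negative (errors
   faster) under speed stress, where most errors are guesses, positive
   under accuracy stress, where drift variability makes diffusion errors
   slow;
2. the coefficient of variation SD(RT)/mean(RT) is U-shaped, large where
   guesses widen the distribution, large again where wide boundaries do;
3. RT skewness is likewise U-shaped.

Moment skewness is notoriously outlier- and cutoff-sensitive, so the
robust quartile skewness (Q3 + Q1 - 2 Q2)/(Q3 - Q1) and Pearson skewness
3 (mean - median)/SD are computed alongside it.  A one-sample t-test of
per-subject accuracy against 0.5 for sub-300-ms responses checks the
chance-accuracy signature of fast guesses, and quantile-probability-plot
tables summarise accuracy and RT-distribution shape jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import mixture_accuracy
from .params import DesignParams, N_CONTRAST, N_SPEED

__all__ = [
    "error_correct_rt_diff",
    "cv_ratio",
    "skewness_measures",
    "SkewnessMeasures",
    "benchmark_table",
    "chance_accuracy_test",
    "ChanceAccuracyResult",
    "qpp_table",
    "qpp_table_model",
]

#: Per-response observation count above which QPP rows report quantiles;
#: at or below it only the median is reported.
QPP_MIN_N = 15

QPP_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)


def error_correct_rt_diff(trials: pd.DataFrame) -> float:
    """Mean error RT minus mean correct RT; NaN if either type is absent."""
    err = trials.loc[trials["correct"] == 0, "rt_s"]
    cor = trials.loc[trials["correct"] == 1, "rt_s"]
    if len(err) == 0 or len(cor) == 0:
        return float("nan")
    return float(err.mean() - cor.mean())


def cv_ratio(rts) -> float:
    """SD(RT) / mean(RT); NaN for fewer than 2 observations.

    Scale-invariant: multiplying all RTs by a constant leaves it
    unchanged.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        return float("nan")
    return float(np.std(rts, ddof=1) / np.mean(rts))


@dataclass
class SkewnessMeasures:
    moment: float     # third standardized central moment
    quartile: float   # (Q3 + Q1 - 2 Q2) / (Q3 - Q1), in [-1, 1]
    pearson: float    # 3 (mean - median) / SD


def skewness_measures(rts) -> SkewnessMeasures:
    """Moment, quartile and Pearson skewness of an RT sample (n >= 4)."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < 4 or np.ptp(rts) == 0:
        return SkewnessMeasures(float("nan"), float("nan"), float("nan"))
    moment = float(stats.skew(rts, bias=True))
    q1, q2, q3 = np.quantile(rts, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    quartile = float((q3 + q1 - 2.0 * q2) / iqr) if iqr > 0 else float("nan")
    sd = float(np.std(rts, ddof=1))
    pearson = float(3.0 * (np.mean(rts) - q2) / sd) if sd > 0 else float("nan")
    return SkewnessMeasures(moment=moment, quartile=quartile, pearson=pearson)


def benchmark_table(trials: pd.DataFrame, mode: str = "per_subject") -> pd.DataFrame:
    """Benchmark statistics per speed condition (collapsed over contrast).

    ``mode="per_subject"`` (default) computes each statistic per subject
    and speed condition and averages across subjects; ``mode="pooled"``
    pools all subjects' trials first.  Correct and error RTs are pooled
    for the CV and skewness columns; the error-correct difference splits
    them by definition.
    """
    if mode not in ("per_subject", "pooled"):
        raise ValueError("mode must be 'per_subject' or 'pooled'")

    def _stats(group: pd.DataFrame) -> pd.Series:
        rts = group["rt_s"].to_numpy()
        sk = skewness_measures(rts)
        return pd.Series(
            {
                "err_minus_corr_rt": error_correct_rt_diff(group),
                "cv": cv_ratio(rts),
                "skew_moment": sk.moment,
                "skew_quartile": sk.quartile,
                "skew_pearson": sk.pearson,
            }
        )

    if mode == "pooled":
        out = trials.groupby("speed_cond").apply(_stats, include_groups=False)
    else:
        per = trials.groupby(["subject", "speed_cond"]).apply(_stats, include_groups=False)
        out = per.groupby(level="speed_cond").mean()
    return out.reset_index()


@dataclass
class ChanceAccuracyResult:
    t_stat: float
    p_value: float
    cohens_d: float
    df: int
    n_subjects: int
    mean_accuracy: float
    subject_accuracy: pd.Series
    excluded_subjects: list


def chance_accuracy_test(
    trials: pd.DataFrame,
    rt_cutoff: float | None = 0.3,
    speed_conds=(1,),
) -> ChanceAccuracyResult:
    """One-sample t-test of per-subject accuracy against chance (0.5).

    Restricted to the given speed conditions and, when ``rt_cutoff`` is
    not None, to responses faster than the cutoff (the fast-guess
    window).  Cohen's d is |mean - 0.5| divided by the between-subject
    SD; subjects with no qualifying trials are excluded and listed.
    """
    sel = trials[trials["speed_cond"].isin(speed_conds)]
    if rt_cutoff is not None:
        sel = sel[sel["rt_s"] < rt_cutoff]
    acc = sel.groupby("subject")["correct"].mean()
    all_subjects = trials["subject"].unique()
    excluded = sorted(set(all_subjects) - set(acc.index))
    if len(acc) < 2:
        raise ValueError("need at least 2 subjects with qualifying trials")
    sd = float(np.std(acc.to_numpy(), ddof=1))
    if sd == 0.0:
        # degenerate: every subject identical; t is 0/0 at exact chance
        delta = float(acc.mean() - 0.5)
        t_stat = 0.0 if delta == 0.0 else float(np.inf) * np.sign(delta)
        p_val = 1.0 if delta == 0.0 else 0.0
        d = 0.0 if delta == 0.0 else float("inf")
    else:
        tt = stats.ttest_1samp(acc.to_numpy(), 0.5)
        t_stat, p_val = float(tt.statistic), float(tt.pvalue)
        d = float(abs(acc.mean() - 0.5) / sd)
    return ChanceAccuracyResult(
        t_stat=t_stat,
        p_value=p_val,
        cohens_d=d,
        df=len(acc) - 1,
        n_subjects=len(acc),
        mean_accuracy=float(acc.mean()),
        subject_accuracy=acc,
        excluded_subjects=excluded,
    )


def qpp_table(trials: pd.DataFrame, min_n: int = QPP_MIN_N, probs=QPP_PROBS) -> pd.DataFrame:
    """Quantile-probability-plot table from trial data.

    One row per (speed, contrast, response): the response proportion and
    the RT quantiles, or the median only when the response has ``min_n``
    or fewer observations (rows need at least one observation; empty
    combinations are omitted).
    """
    rows = []
    qcols = [f"q{int(100 * p)}" for p in probs]
    for (speed, contrast), cell in trials.groupby(["speed_cond", "contrast_cond"]):
        n_cell = len(cell)
        for resp, is_corr in (("correct", 1), ("error", 0)):
            rts = cell.loc[cell["correct"] == is_corr, "rt_s"].to_numpy()
            if rts.size == 0:
                continue
            row = {
                "speed_cond": speed,
                "contrast_cond": contrast,
                "response": resp,
                "n": rts.size,
                "prop": rts.size / n_cell,
            }
            if rts.size > min_n:
                row.update(dict(zip(qcols, np.quantile(rts, probs))))
            else:
                row["q50"] = float(np.median(rts))
            rows.append(row)
    return pd.DataFrame(rows, columns=["speed_cond", "contrast_cond", "response", "n", "prop", *qcols])


def qpp_table_model(design: DesignParams, probs=QPP_PROBS, gh_order: int = 20) -> pd.DataFrame:
    """Model-side quantile-probability table from design parameters.

    Response proportions are the mixture accuracies p_o/2 + (1 - p_o)
    P_diff; quantiles of each response's RT distribution are found by
    bisection on the mixture defective CDF.
    """
    from scipy.optimize import brentq

    from .mixture import mixture_defective_cdf

    rows = []
    qcols = [f"q{int(100 * p)}" for p in probs]
    for speed in range(1, N_SPEED + 1):
        for contrast in range(1, N_CONTRAST + 1):
            cond = design.condition(speed, contrast)
            acc = mixture_accuracy(cond, gh_order=gh_order)
            for resp, p_resp in (("correct", acc), ("error", 1.0 - acc)):
                row = {
                    "speed_cond": speed,
                    "contrast_cond": contrast,
                    "response": resp,
                    "prop": p_resp,
                }
                for p, col in zip(probs, qcols):
                    target = p * p_resp
                    row[col] = brentq(
                        lambda t: float(
                            mixture_defective_cdf(t, cond, resp, gh_order=gh_order)
                        ) - target,
                        1e-4, 20.0, xtol=1e-5,
                    )
                rows.append(row)
    return pd.DataFrame(rows, columns=["speed_cond", "contrast_cond", "response", "prop", *qcols])
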