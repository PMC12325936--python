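"""Circular error summaries and group comparisons.

Absolute errors of circadian-time estimates are rarely normally
distributed, so the headline summary is the median absolute error
(MdAE) with the standard deviation of absolute errors alongside the
MAE and mean signed error.  Group comparisons use the Mann-Whitney U
test for independent groups and the Wilcoxon signed-rank test for
paired ones, with Bonferroni adjustment over an explicit family size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .timecodec import signed_circular_error


@dataclass
class ErrorSummary:
    n: int
    mdae_min: float
    mae_min: float
    sd_abs_min: float
    mean_signed_min: float
    signed_min: np.ndarray
    abs_min: np.ndarray


def summarize_errors(estimates, truths) -> ErrorSummary:
    """Circular error summary of paired estimates and truths (minutes)."""
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape:
        raise ValueError("estimates and truths must be paired")
    signed = signed_circular_error(estimates, truths)
    ab = np.abs(signed)
    return ErrorSummary(
        n=len(signed),
        mdae_min=float(np.median(ab)),
        mae_min=float(np.mean(ab)),
        sd_abs_min=float(np.std(ab, ddof=1)) if len(ab) > 1 else 0.0,
        mean_signed_min=float(np.mean(signed)),
        signed_min=signed,
        abs_min=ab,
    )


def compare_groups(a, b, paired: bool = False, family_size: int = 1,
                   alternative: str = "two-sided") -> dict:
    """Nonparametric comparison of two error groups.

    Wilcoxon signed-rank when ``paired`` (equal lengths required),
    Mann-Whitney U otherwise.  The Bonferroni family size is an
    explicit parameter, never inferred.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired groups must have equal length")
        if np.allclose(a, b):
            stat, p = np.nan, 1.0
        else:
            res = stats.wilcoxon(a, b, alternative=alternative)
            stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon_signed_rank"
    else:
        res = stats.mannwhitneyu(a, b, alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "mann_whitney_u"
    return {
        "test": test,
        "statistic": stat,
        "p_raw": p,
        "p_adjusted": min(1.0, p * family_size),
        "family_size": family_size,
        "paired": paired,
    }


def period_from_two_timepoints(err_zt0_min: float, err_zt12_min: float) -> float:
    """Clock period (hours) read from signed errors 12 h apart.

    A linear drift model on an idealised 24-h reference: the error
    accumulated between the two timepoints doubles over a full cycle,
    so period = 24 - (err12 - err0)/60 * 2.  An advance accumulating
    through the day reads as a short period, a delay as a long one.
    """
    drift_h = (float(err_zt12_min) - float(err_zt0_min)) / 60.0
    return 24.0 - drift_h * (24.0 / 12.0)
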