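"""Method-comparison statistics: regression, paired t, Bland-Altman, RPC.

The repeatability coefficient (RPC) is two times the SD of the paired
differences, or — when the difference-vs-mean correlation is significant
(a proportional error) — two times the SD of the residuals of the linear
regression in the Bland-Altman plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class AgreementReport:
    n: int
    slope: float  # regression of method B on method A
    intercept: float
    r: float
    p_regression: float
    mean_diff: float  # mean of a - b
    sd_diff: float
    p_paired_t: float  # NaN when differences have zero variance
    p_proportional: float  # NaN when undefined
    proportional_error: bool
    rpc: float
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "p_regression": self.p_regression,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "p_paired_t": self.p_paired_t,
            "p_proportional": self.p_proportional,
            "proportional_error": self.proportional_error,
            "rpc": self.rpc,
            "loa_lower": self.mean_diff - 2 * self.sd_diff,
            "loa_upper": self.mean_diff + 2 * self.sd_diff,
            "alpha": self.alpha,
        }


def _as_pair(a, b) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
        raise ValueError("inputs must be 1D arrays of equal length")
    return a, b


def linear_fit(x, y) -> Tuple[float, float, float, float]:
    """OLS of y on x: (slope, intercept, Pearson r, two-sided p for r != 0)."""
    x, y = _as_pair(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)


def paired_t(a, b) -> Tuple[float, float]:
    """Two-sided paired t-test on a - b: (t, p)."""
    a, b = _as_pair(a, b)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance differences; paired t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def bland_altman(a, b, alpha: float = 0.05) -> AgreementReport:
    """Bland-Altman agreement of paired measurements a and b.

    Differences ``d = a - b`` are compared against means ``m = (a + b)/2``;
    a significant Pearson correlation of (m, d) flags a proportional error
    and switches the RPC to the residual-SD form. Identical inputs are a
    legitimate degenerate case (rpc 0, no proportional error).
    """
    a, b = _as_pair(a, b)
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    d = a - b
    m = (a + b) / 2.0
    mean_diff = float(d.mean())
    sd_diff = float(np.std(d, ddof=1))

    slope, intercept, r, p_regression = linear_fit(a, b)

    if sd_diff == 0:
        p_paired = math.nan
        p_prop = math.nan
        proportional = False
        rpc = 0.0
    else:
        _, p_paired = paired_t(a, b)
        if np.ptp(m) == 0:
            p_prop = math.nan
            proportional = False
        else:
            _, p_prop = stats.pearsonr(m, d)
            p_prop = float(p_prop)
            proportional = p_prop < alpha
        if proportional:
            ba_slope, ba_intercept, _, _ = linear_fit(m, d)
            residuals = d - (ba_slope * m + ba_intercept)
            rpc = 2.0 * float(np.std(residuals, ddof=1))
        else:
            rpc = 2.0 * sd_diff

    return AgreementReport(
        n=int(a.size),
        slope=slope,
        intercept=intercept,
        r=r,
        p_regression=p_regression,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        p_paired_t=float(p_paired),
        p_proportional=float(p_prop),
        proportional_error=proportional,
        rpc=rpc,
        alpha=alpha,
    )
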