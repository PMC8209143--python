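"""Model-evaluation statistics and the first-cut phenology shift analysis.

Conventions, fixed and documented: sample (n-1) standard deviations
throughout; linear-interpolation quantiles (numpy default); r2 is the
squared correlation of an ordinary least-squares fit of simulated on
observed (identical to squared Pearson r for a simple regression with
intercept).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSeries",
    "ErrorMetrics",
    "error_metrics",
    "variability",
    "paired_t_and_correlation",
    "first_cut_shift_per_degC",
    "concordance_ccc",
]


@dataclass(frozen=True)
class PairedSeries:
    """Aligned observed/simulated vectors with optional labels."""

    observed: np.ndarray
    simulated: np.ndarray
    labels: tuple = ()

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        sim = np.asarray(self.simulated, dtype=float)
        if obs.shape != sim.shape or obs.ndim != 1:
            raise ValueError("observed and simulated must be equal-length 1-D vectors")
        if len(obs) < 2:
            raise ValueError("need at least 2 pairs")
        if np.any(~np.isfinite(obs)) or np.any(~np.isfinite(sim)):
            raise ValueError("missing/non-finite entries after alignment")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "simulated", sim)


class ErrorMetrics(NamedTuple):
    rmse: float
    nrmse: float
    r2: float
    ccc: float


def concordance_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (sample-covariance
    convention): penalizes scatter as well as location and scale shift;
    symmetric in its arguments and never larger than |Pearson r|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    sx2 = np.var(x, ddof=1)
    sy2 = np.var(y, ddof=1)
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return 1.0
    return float(2.0 * sxy / denom)


def error_metrics(pairs: PairedSeries) -> ErrorMetrics:
    """RMSE (data units), NRMSE = RMSE / mean(observed), OLS r2 of simulated
    on observed, and Lin's CCC."""
    obs, sim = pairs.observed, pairs.simulated
    if len(obs) < 3:
        raise ValueError("need at least 3 pairs for error metrics")
    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    mean_obs = float(np.mean(obs))
    if mean_obs == 0:
        raise ZeroDivisionError("NRMSE undefined: observed mean is zero")
    res = sps.linregress(obs, sim)
    return ErrorMetrics(rmse, rmse / mean_obs, float(res.rvalue**2),
                        concordance_ccc(obs, sim))


def variability(series, by_period: Sequence | None = None) -> dict:
    """Coefficient of variation (sample SD / mean) per period.

    ``by_period`` assigns a period label to each value; ``None`` treats the
    whole series as one period keyed ``"all"``."""
    values = np.asarray(series, dtype=float)
    if by_period is None:
        by_period = ["all"] * len(values)
    out: dict = {}
    for period in dict.fromkeys(by_period):  # preserve order
        v = values[np.asarray([p == period for p in by_period])]
        if len(v) < 2:
            raise ValueError(f"period {period!r} needs at least 2 values")
        mean = v.mean()
        if mean == 0:
            raise ZeroDivisionError(f"CV undefined for period {period!r}: zero mean")
        out[period] = float(np.std(v, ddof=1) / mean)
    return out


class PairedTestResult(NamedTuple):
    t_statistic: float
    t_pvalue: float
    correlation: float
    correlation_pvalue: float
    method: str               # "pearson" | "spearman"
    normal_observed: bool
    normal_simulated: bool


def paired_t_and_correlation(pairs: PairedSeries, alpha: float = 0.05) -> PairedTestResult:
    """Paired t-test on the differences plus a normality-routed correlation:
    Shapiro-Wilk on each margin, Pearson if both pass at ``alpha``, else
    Spearman."""
    obs, sim = pairs.observed, pairs.simulated
    if len(obs) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(obs) == 0 or np.ptp(sim) == 0:
        raise ValueError("correlation undefined for constant input")
    norm_obs = sps.shapiro(obs).pvalue > alpha
    norm_sim = sps.shapiro(sim).pvalue > alpha
    if norm_obs and norm_sim:
        r = sps.pearsonr(obs, sim)
        method = "pearson"
    else:
        r = sps.spearmanr(obs, sim)
        method = "spearman"
    diffs = obs - sim
    if np.ptp(diffs) == 0 and diffs[0] == 0:
        # identical pairs: zero differences, no evidence of a shift
        t = type("T", (), {"statistic": 0.0, "pvalue": 1.0})
    else:
        t = sps.ttest_rel(obs, sim)
    return PairedTestResult(float(t.statistic), float(t.pvalue),
                            float(r.statistic), float(r.pvalue),
                            method, norm_obs, norm_sim)


def first_cut_shift_per_degC(
    first_cut_doys_a: Sequence[float],
    first_cut_doys_b: Sequence[float],
    mat_a: Sequence[float],
    mat_b: Sequence[float],
    quantiles: tuple[float, float] = (25.0, 75.0),
) -> tuple[float, ...]:
    """Advance of the first cut per degree of warming between two periods.

    For each quantile q the shift is ``Q_q(period a DOYs) - Q_q(period b
    DOYs)`` divided by ``mean(MAT_b) - mean(MAT_a)`` where period a is the
    earlier and b the later period.  Positive values mean the first cut
    moves *earlier* by that many days per +1 degC (tabulations that report
    shifts as negative numbers use the opposite sign).  Antisymmetric under
    swapping the periods.
    """
    a = np.asarray(first_cut_doys_a, dtype=float)
    b = np.asarray(first_cut_doys_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both periods must be non-empty")
    d_mat = float(np.mean(mat_b) - np.mean(mat_a))
    if d_mat == 0:
        raise ZeroDivisionError("temperature change between periods is zero")
    return tuple(
        float((np.percentile(a, q) - np.percentile(b, q)) / d_mat)
        for q in quantiles
    )
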