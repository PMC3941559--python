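"""Validation statistics: Pearson correlation, Bland-Altman agreement, summaries.

Agreement between the photogrammetric predictions and spirometry follows
the Bland-Altman convention: the bias is the mean of paired differences
(method1 − method2) and the limits of agreement are bias ± 1.96·SD of the
differences, with SD using the sample (n−1) denominator.  The companion
test for a non-zero bias is a two-sided one-sample t-test at α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

#: Fixed limits-of-agreement multiplier (the conventional 95% normal quantile).
LOA_FACTOR = 1.96

ALPHA = 0.05


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, spread and limits of agreement for one pair of methods."""

    bias: float
    sd_diff: float
    ULA: float
    LLA: float
    bias_p_value: float
    means: np.ndarray = field(repr=False, compare=False, default=None)
    diffs: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.ULA < self.LLA:
            raise ParameterError("upper limit of agreement below lower limit")


def pearson_r(x, y) -> float:
    """Sample Pearson correlation between two equally long vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ParameterError("correlation needs at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("correlation is undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(method1, method2) -> BlandAltmanResult:
    """Agreement between two measurement methods on paired values.

    Differences are method1 − method2; the per-pair means are stored for
    plotting.  With zero-variance differences the t-test degenerates and
    the p-value is reported as 1.0 for zero bias, 0.0 otherwise.
    """
    m1 = np.asarray(method1, dtype=float)
    m2 = np.asarray(method2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ParameterError("methods must be 1-D vectors of equal length")
    if m1.size < 3:
        raise ParameterError("agreement needs at least 3 paired observations")

    diffs = m1 - m2
    means = (m1 + m2) / 2.0
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    if sd == 0:
        p = 1.0 if bias == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        ULA=bias + LOA_FACTOR * sd,
        LLA=bias - LOA_FACTOR * sd,
        bias_p_value=p,
        means=means,
        diffs=diffs,
    )


def correlation_table(photogrammetric: pd.DataFrame, spirometric: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between each photogrammetric quantity and each spirometric outcome.

    Rows follow the photogrammetric column order (per-compartment volumes,
    totals, mobility); columns the spirometric outcome order (FEV1, FVC,
    PEF, DI).
    """
    if len(photogrammetric) != len(spirometric):
        raise ParameterError("photogrammetric and spirometric tables must align by subject")
    table = pd.DataFrame(
        index=photogrammetric.columns, columns=spirometric.columns, dtype=float
    )
    for p in photogrammetric.columns:
        for s in spirometric.columns:
            table.loc[p, s] = pearson_r(photogrammetric[p], spirometric[s])
    return table


def summarize_cohort(values: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Mean / SD / min / max per variable, one row each.

    SD uses the sample (n−1) denominator; a single-subject cohort reports
    SD = 0 with mean = min = max.
    """
    if values.empty:
        raise ParameterError("cannot summarize an empty cohort")
    cols = variables if variables is not None else list(values.columns)
    rows = []
    for name in cols:
        v = values[name].to_numpy(dtype=float)
        sd = 0.0 if v.size == 1 else float(np.std(v, ddof=1))
        rows.append(
            {
                "variable": name,
                "mean": float(np.mean(v)),
                "sd": sd,
                "min": float(np.min(v)),
                "max": float(np.max(v)),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def plot_bland_altman(result: BlandAltmanResult, outcome: str, path) -> None:
    """Scatter of per-pair means vs differences with bias, ULA and LLA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.diffs, s=18, color="k", zorder=3)
    ax.axhline(result.bias, color="tab:blue", lw=1.2, label=f"bias = {result.bias:.3f} l")
    ax.axhline(
        result.ULA, color="tab:red", ls="--", lw=1.0, label=f"ULA = {result.ULA:.3f} l"
    )
    ax.axhline(
        result.LLA, color="tab:red", ls="--", lw=1.0, label=f"LLA = {result.LLA:.3f} l"
    )
    ax.set_xlabel(f"mean of methods ({outcome}, l)")
    ax.set_ylabel("difference photogrammetry − spirometry (l)")
    ax.set_title(f"Bland-Altman agreement: {outcome}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
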