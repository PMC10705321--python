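"""Agreement statistics and study reports.

Quantifies how well calculated ratio-of-ratios values agree with the bench
ground truth: mean absolute error, squared Pearson correlation, and
Bland-Altman bias with 1.96-SD limits of agreement; paired t-tests compare
per-segment absolute errors between capture settings.  R-squared is the
squared Pearson correlation between calculated and true values (not a
y = x residual definition, which would be negative for a setting with a
systematic multiplicative distortion yet high correlation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ReportError

#: Report row order for the three capture settings under comparison.
DEFAULT_SETTINGS = ("Default automatic", "Uncalibrated linear", "Calibrated linear")

_LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementStats:
    """Agreement of a calculated series with ground truth."""

    mae: float
    r_squared: float
    bias: float
    loa_lower: float
    loa_upper: float
    n: int


@dataclass(frozen=True)
class PairedComparison:
    """Paired comparison of per-segment absolute errors (b against baseline a)."""

    mean_abs_error_a: float
    mean_abs_error_b: float
    percent_reduction: float
    t_statistic: float
    p_value: float


def agreement(calculated: Sequence[float], truth: Sequence[float]) -> AgreementStats:
    """MAE, squared Pearson correlation, and Bland-Altman bias / LoA.

    Differences are calculated minus truth; limits of agreement are
    bias +/- 1.96 times the sample (n-1) standard deviation.

    Raises
    ------
    ReportError
        If lengths differ, fewer than 3 pairs are given, or either series
        has zero variance (correlation undefined).
    """
    c = np.asarray(calculated, dtype=float)
    t = np.asarray(truth, dtype=float)
    if c.shape != t.shape or c.ndim != 1:
        raise ReportError("calculated and truth must be equal-length 1-D sequences")
    if len(c) < 3:
        raise ReportError("need at least 3 pairs for agreement statistics")
    if np.ptp(c) == 0.0 or np.ptp(t) == 0.0:
        raise ReportError("zero variance: correlation is undefined")
    d = c - t
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    r = float(np.corrcoef(c, t)[0, 1])
    return AgreementStats(
        mae=float(np.mean(np.abs(d))),
        r_squared=r * r,
        bias=bias,
        loa_lower=bias - _LOA_MULTIPLIER * sd,
        loa_upper=bias + _LOA_MULTIPLIER * sd,
        n=len(c),
    )


def compare_paired(
    abs_err_a: Sequence[float], abs_err_b: Sequence[float]
) -> PairedComparison:
    """Two-sided paired t-test on absolute errors, plus percent reduction.

    ``a`` is the baseline: percent_reduction = 100 * (1 - mean(b)/mean(a)).
    If every paired difference is zero the test is degenerate and p = 1.

    Raises
    ------
    ReportError
        If lengths differ or fewer than 3 pairs are given.
    """
    a = np.asarray(abs_err_a, dtype=float)
    b = np.asarray(abs_err_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ReportError("paired error sequences must be equal-length 1-D")
    if len(a) < 3:
        raise ReportError("need at least 3 pairs for a paired t-test")
    mean_a = float(np.mean(a))
    mean_b = float(np.mean(b))
    d = b - a
    if np.all(d == 0.0):
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_rel(b, a)
        t_stat, p = float(res.statistic), float(res.pvalue)
    reduction = 100.0 * (1.0 - mean_b / mean_a) if mean_a != 0 else np.nan
    return PairedComparison(
        mean_abs_error_a=mean_a,
        mean_abs_error_b=mean_b,
        percent_reduction=reduction,
        t_statistic=t_stat,
        p_value=p,
    )


_METRICS = ("MAE", "R2", "Bias", "LoA lower", "LoA upper")


def _stat_value(s: AgreementStats, metric: str) -> float:
    return {
        "MAE": s.mae,
        "R2": s.r_squared,
        "Bias": s.bias,
        "LoA lower": s.loa_lower,
        "LoA upper": s.loa_upper,
    }[metric]


def build_report(
    tables: Mapping[str, Mapping[str, Tuple[Sequence[float], Sequence[float]]]],
    settings: Sequence[str] = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Assemble the per-device agreement table across capture settings.

    ``tables`` maps device name -> setting name -> (calculated, truth)
    series.  The result has a (metric, setting) row MultiIndex and one
    column per device plus cross-device ``Mean`` and ``STD`` columns
    (STD is NaN for a single device).

    Raises
    ------
    ReportError
        If no devices are given or a device is missing a setting.
    """
    if not tables:
        raise ReportError("no devices to report on")
    per_device: Dict[str, Dict[str, AgreementStats]] = {}
    for device, by_setting in tables.items():
        per_device[device] = {}
        for setting in settings:
            if setting not in by_setting:
                raise ReportError(f"device {device!r} is missing setting {setting!r}")
            calc, truth = by_setting[setting]
            per_device[device][setting] = agreement(calc, truth)

    index = pd.MultiIndex.from_product([_METRICS, settings], names=["metric", "setting"])
    df = pd.DataFrame(index=index, columns=list(tables), dtype=float)
    for device, by_setting in per_device.items():
        for setting, s in by_setting.items():
            for metric in _METRICS:
                df.loc[(metric, setting), device] = _stat_value(s, metric)
    device_cols = list(tables)
    df["Mean"] = df[device_cols].mean(axis=1)
    df["STD"] = df[device_cols].std(axis=1, ddof=1) if len(device_cols) > 1 else np.nan
    return df


def report_text(report: pd.DataFrame, header: str = "") -> str:
    """Human-readable rendering of a report table."""
    lines = []
    if header:
        lines.append(header)
    lines.append(report.to_string(float_format=lambda v: f"{v:.4f}"))
    return "\n".join(lines) + "\n"


def plot_agreement(
    calculated: Sequence[float],
    truth: Sequence[float],
    path,
    title: str = "",
) -> None:
    """Correlation (with dashed y = x) and Bland-Altman plot side by side."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    s = agreement(calculated, truth)
    c = np.asarray(calculated, float)
    t = np.asarray(truth, float)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(t, c, s=12)
    lims = [min(t.min(), c.min()), max(t.max(), c.max())]
    ax1.plot(lims, lims, "k--", lw=1)
    ax1.set_xlabel("Ground truth RoR")
    ax1.set_ylabel("Calculated RoR")
    ax1.set_title(f"{title} (R$^2$={s.r_squared:.2f}, MAE={s.mae:.3f})".strip())
    mean_ct = (c + t) / 2
    ax2.scatter(mean_ct, c - t, s=12)
    ax2.axhline(s.bias, ls="--", color="k", lw=1)
    ax2.axhline(s.loa_lower, ls=":", color="k", lw=1)
    ax2.axhline(s.loa_upper, ls=":", color="k", lw=1)
    ax2.set_xlabel("Mean of calculated and truth")
    ax2.set_ylabel("Difference (calc - truth)")
    ax2.set_title("Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
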