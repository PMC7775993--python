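"""Scan-rescan repeatability and cross-method reproducibility statistics.

For paired measurements (x_i1, x_i2) of one metric in one region across
subjects i = 1..n:

* wCV — within-subject coefficient of variation, the two-replicate
  root-mean-square within-subject SD over the grand mean, in percent:
  ``sqrt(mean_i(d_i^2 / 2)) / mean(x) * 100`` with d_i = x_i1 - x_i2.
* ICC(2,1) — two-way random-effects, absolute-agreement, single-measurement
  intraclass correlation from the ANOVA mean squares, with the Cicchetti
  interpretation bands (poor < 0.40 <= fair < 0.60 <= good < 0.75 <=
  excellent).
* Bland-Altman — bias = mean(d_i), limits of agreement bias ± 1.96 * SD(d_i)
  (sample SD, n-1 denominator).
* Percent relative difference — |a - b| over the symmetric mean (a + b)/2,
  in percent, for cross-method comparison of per-region averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReliabilityReport",
    "wcv",
    "icc_agreement",
    "cicchetti_category",
    "bland_altman",
    "percent_relative_difference",
    "reliability_report",
    "bland_altman_figure",
]


@dataclass(frozen=True)
class ReliabilityReport:
    """Per-region, per-metric reliability summary."""

    metric: str
    wcv_percent: float
    icc: float
    icc_category: str
    bias: float
    loa_lower: float
    loa_upper: float
    n: int
    icc_degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "wcv_percent": self.wcv_percent,
            "icc": self.icc,
            "icc_category": self.icc_category,
            "bias": self.bias,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "n": self.n,
        }


def _as_pairs(pairs: np.ndarray) -> np.ndarray:
    p = np.asarray(pairs, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
        raise ValueError("pairs must be an (n >= 2, 2) array")
    return p


def wcv(pairs: np.ndarray) -> float:
    """Within-subject coefficient of variation, percent (two replicates).

    Scale-invariant: multiplying all values by a constant leaves it
    unchanged.  Requires strictly positive measurements.
    """
    p = _as_pairs(pairs)
    if np.any(p <= 0):
        raise ValueError("wCV requires strictly positive measurements")
    d = p[:, 0] - p[:, 1]
    within_sd = np.sqrt(np.mean(d**2 / 2.0))
    return float(within_sd / p.mean() * 100.0)


def icc_agreement(ratings: np.ndarray) -> tuple[float, bool]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is subjects x raters (n x k).  Computed from the two-way
    ANOVA mean squares::

        ICC = (MS_R - MS_E) /
              (MS_R + (k-1) MS_E + k/n (MS_C - MS_E))

    A fully degenerate table (zero total variance) is defined as perfect
    agreement; the second return value flags that case.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (subjects >= 2) x (raters >= 2)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    # residual form (not total - rows - cols): exact zero for exact agreement
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    ss_total = np.sum((x - grand) ** 2)
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e)
    if denom <= 0 or ss_total == 0:
        return 1.0, True  # no variance anywhere: agreement is perfect by definition
    return float((ms_r - ms_e) / denom), False


def cicchetti_category(icc: float) -> str:
    """Interpretation band of an agreement ICC (lower edges inclusive)."""
    if icc > 1.0:
        raise ValueError("ICC cannot exceed 1")
    if icc >= 0.75:
        return "excellent"
    if icc >= 0.60:
        return "good"
    if icc >= 0.40:
        return "fair"
    return "poor"


def bland_altman(pairs: np.ndarray) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of paired differences.

    Returns ``(bias, loa_lower, loa_upper)`` with
    ``loa = bias ± 1.96 * SD(d)`` (sample SD, n-1 denominator).
    """
    p = _as_pairs(pairs)
    d = p[:, 0] - p[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def percent_relative_difference(a: float, b: float) -> float:
    """|a - b| / ((a + b) / 2) * 100 — symmetric percent difference."""
    if a <= 0 or b <= 0:
        raise ValueError("percent relative difference requires positive inputs")
    return float(abs(a - b) / ((a + b) / 2.0) * 100.0)


def reliability_report(pairs: np.ndarray, metric: str = "") -> ReliabilityReport:
    """Full scan-rescan report for one metric: wCV, ICC(+band), Bland-Altman."""
    p = _as_pairs(pairs)
    icc, degenerate = icc_agreement(p)
    bias, lo, hi = bland_altman(p)
    return ReliabilityReport(
        metric=metric,
        wcv_percent=wcv(p),
        icc=icc,
        icc_category=cicchetti_category(icc),
        bias=bias,
        loa_lower=lo,
        loa_upper=hi,
        n=p.shape[0],
        icc_degenerate=degenerate,
    )


def bland_altman_figure(pairs: np.ndarray, title: str = "", path=None):
    """Bland-Altman scatter (mean vs difference) with bias and LOA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = _as_pairs(pairs)
    mean = p.mean(axis=1)
    diff = p[:, 0] - p[:, 1]
    bias, lo, hi = bland_altman(p)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=0.8)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
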