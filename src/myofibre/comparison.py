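"""Method-comparison statistics: Bland–Altman, normality screen, t-test.

Automated morphometry is validated against a reference (usually manual)
measurement with the Bland–Altman procedure: the bias is the mean of
the paired differences and the limits of agreement, bias ± 1.96 × SD of
the differences, bracket ~95 % of paired differences when those are
normally distributed.  The sign convention here is fixed as
``automated − manual`` (method_b − method_a).

The normality screen is the Kolmogorov–Smirnov test in its Lilliefors
variant (mean and SD estimated from the data), with the p-value from
the Dallal–Wilkinson (1986) approximation.  Group contrasts use the
unpaired Student's t-test with pooled variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import DimensionError

__all__ = [
    "PairedMeasurements",
    "BlandAltmanResult",
    "bland_altman",
    "ks_normality",
    "two_sample_t",
]


@dataclass
class PairedMeasurements:
    """Paired readings of one quantity by two methods.

    ``method_a`` is the reference (manual) series, ``method_b`` the
    automated one; differences are oriented b − a.
    """

    method_a: np.ndarray
    method_b: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=float)
        self.method_b = np.asarray(self.method_b, dtype=float)
        if self.method_a.shape != self.method_b.shape or self.method_a.ndim != 1:
            raise DimensionError(
                "paired series must be 1-D and of equal length, got "
                f"{self.method_a.shape} and {self.method_b.shape}"
            )
        if len(self.method_a) < 2:
            raise ValueError("Bland-Altman needs at least 2 pairs")
        if not (np.all(np.isfinite(self.method_a)) and np.all(np.isfinite(self.method_b))):
            raise ValueError("paired measurements must be finite")


@dataclass
class BlandAltmanResult:
    """Bias and 95 % limits of agreement, plus the plot data."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray
    diffs: np.ndarray
    label: str = ""


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland–Altman agreement analysis of two measurement methods.

    Differences are method_b − method_a; the limits of agreement are
    bias ± 1.96 sample SD of the differences (the large-sample 95 %
    bracket).
    """
    diffs = pairs.method_b - pairs.method_a
    means = (pairs.method_a + pairs.method_b) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        means=means,
        diffs=diffs,
        label=pairs.label,
    )


def _lilliefors_p(d: float, n: int) -> float:
    """Dallal–Wilkinson approximation to the Lilliefors p-value."""
    if n > 100:
        kd = d * (n / 100.0) ** 0.49
        nd = 100
    else:
        kd, nd = d, n
    p = np.exp(
        -7.01256 * kd**2 * (nd + 2.78019)
        + 2.99587 * kd * np.sqrt(nd + 2.78019)
        - 0.122119
        + 0.974598 / np.sqrt(nd)
        + 1.67997 / nd
    )
    if p <= 0.1:
        return float(min(p, 1.0))
    # outside the exponential's validity range: polynomial interpolation
    kk = (np.sqrt(n) - 0.01 + 0.85 / np.sqrt(n)) * d
    if kk <= 0.302:
        return 1.0
    if kk <= 0.5:
        p = 2.76773 - 19.828315 * kk + 80.709644 * kk**2 - 138.55152 * kk**3 + 81.541484 * kk**4
    elif kk <= 0.9:
        p = -4.901232 + 40.662806 * kk - 97.490286 * kk**2 + 94.029866 * kk**3 - 32.355711 * kk**4
    elif kk <= 1.31:
        p = 6.198765 - 19.558097 * kk + 23.186922 * kk**2 - 12.234627 * kk**3 + 2.423045 * kk**4
    else:
        p = 0.0
    return float(min(max(p, 0.0), 1.0))


def ks_normality(values) -> tuple[float, float]:
    """Lilliefors-type Kolmogorov–Smirnov normality test.

    D = sup |empirical CDF − Normal(μ̂, σ̂) CDF| with both moments
    estimated from the data (sample SD); p-value by the
    Dallal–Wilkinson approximation.  Requires n ≥ 5.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError("KS normality test needs at least 5 values")
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        raise ValueError("KS normality test undefined for constant data")
    cdf = stats.norm.cdf((x - mu) / sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    d = float(max(d_plus, d_minus))
    return d, _lilliefors_p(d, n)


def two_sample_t(group1, group2) -> tuple[float, int, float]:
    """Unpaired Student's t-test with pooled variance.

    Returns (t, degrees of freedom, two-sided p).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(g1, g2, equal_var=True)
    return float(res.statistic), int(g1.size + g2.size - 2), float(res.pvalue)
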