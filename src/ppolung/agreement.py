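"""Agreement statistics between predicted and observed pulmonary function.

The comparison layer treats each (method, measure) pairing as a paired series
of predicted postoperative values ``x`` and observed postoperative values
``y`` (both % of predicted, 0–100 scale). Throughout the package, paired
differences are ``observed − predicted`` (``y − x``): a positive mean
difference means the prediction *under*-estimates the observed value.

Statistics provided:

* Bland–Altman: mean difference, SD (sample, n−1 denominator), SE of the
  mean, and limits of agreement at mean ± 1.96 × SD (fixed multiplier, as
  conventional for limits of agreement).
* Pearson correlation with a two-tailed p from the t distribution on n−2 df.
* Simple OLS of y on x with R² (= r² for simple regression).
* Summary of the absolute differences |y − x|.
* Paired t-test.
* Subgroup filters for impaired-function subsets (strictly below threshold).

All statistics are invariant to record order and operate on pairwise-complete
data (missing values must be dropped by the caller or via
:func:`pairwise_complete`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, ParameterError

__all__ = [
    "BlandAltmanResult",
    "AbsDiffSummary",
    "pairwise_complete",
    "bland_altman",
    "pearson_correlation",
    "regression_r2",
    "absolute_differences",
    "paired_t_test",
    "subgroup_filter",
    "SUBGROUP_CRITERIA",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and limits of agreement for paired measurements."""

    n: int
    mean_difference: float
    sd_difference: float
    se_mean: float
    lower_loa: float
    upper_loa: float


@dataclass(frozen=True)
class AbsDiffSummary:
    n: int
    mean: float
    sd: float
    max: float
    min: float


def pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Drop pairs where either element is missing (None/NaN)."""
    x = np.array([np.nan if v is None else float(v) for v in x])
    y = np.array([np.nan if v is None else float(v) for v in y])
    if x.shape != y.shape:
        raise ParameterError(f"paired series must have equal length: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman analysis of differences ``y − x`` (observed − predicted)."""
    x, y = pairwise_complete(x, y)
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"Bland–Altman needs n >= 2 pairs, got {n}")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        n=n,
        mean_difference=mean,
        sd_difference=sd,
        se_mean=sd / math.sqrt(n),
        lower_loa=mean - LOA_MULTIPLIER * sd,
        upper_loa=mean + LOA_MULTIPLIER * sd,
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment r with a two-tailed p from t on n−2 df."""
    x, y = pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"correlation needs n >= 3 pairs, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("correlation undefined for a zero-variance series")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        return (1.0 if r > 0 else -1.0), 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p


def regression_r2(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: ``(slope, intercept, R²)``.

    A constant y (zero outcome variance) is a valid degenerate fit: slope 0,
    R² 0. A constant x leaves the slope undefined and raises.
    """
    x, y = pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"regression needs n >= 3 pairs, got {n}")
    if x.std() == 0:
        raise DegenerateInputError("regression undefined for zero predictor variance")
    if y.std() == 0:
        return 0.0, float(y[0]), 0.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2


def absolute_differences(x, y) -> AbsDiffSummary:
    """Summary of ``|y − x|``; SD is the sample SD (0.0 when n == 1)."""
    x, y = pairwise_complete(x, y)
    n = len(x)
    if n < 1:
        raise InsufficientDataError("absolute differences need n >= 1 pair")
    a = np.abs(y - x)
    return AbsDiffSummary(
        n=n,
        mean=float(a.mean()),
        sd=float(a.std(ddof=1)) if n > 1 else 0.0,
        max=float(a.max()),
        min=float(a.min()),
    )


def paired_t_test(a, b) -> tuple[float, float]:
    """Paired t-test on differences ``a − b``, two-tailed.

    Identical series return (t=0, p=1); a constant nonzero difference has zero
    variance and no defined t statistic, which raises.
    """
    a, b = pairwise_complete(a, b)
    n = len(a)
    if n < 2:
        raise InsufficientDataError(f"paired t-test needs n >= 2 pairs, got {n}")
    d = a - b
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        raise DegenerateInputError("paired t-test undefined for zero difference variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# subgroup filters
# --------------------------------------------------------------------------

# criterion name -> (record accessor, strict upper threshold)
SUBGROUP_CRITERIA: dict[str, tuple] = {
    "fev1_fvc<70": (lambda r: r.fev1_fvc, 70.0),
    "fev1<80": (lambda r: r.preop.get("fev1"), 80.0),
    "dlco<80": (lambda r: r.preop.get("dlco"), 80.0),
    "dlco_prime<80": (lambda r: r.preop.get("dlco_prime"), 80.0),
}


def subgroup_filter(records, criterion: str):
    """Subset of cohort records strictly below the criterion threshold.

    Records missing the criterion field are excluded. Criteria:
    ``fev1_fvc<70`` (obstructive impairment), ``fev1<80``, ``dlco<80``,
    ``dlco_prime<80`` (diffusion impairment).
    """
    try:
        accessor, threshold = SUBGROUP_CRITERIA[criterion]
    except KeyError:
        raise ParameterError(
            f"unknown criterion {criterion!r}; choose from {sorted(SUBGROUP_CRITERIA)}"
        ) from None
    out = []
    for r in records:
        value = accessor(r)
        if value is not None and value < threshold:
            out.append(r)
    return out
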