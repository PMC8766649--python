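"""ACCP-style risk stratification and diagnostic 2×2 analysis.

A patient is **high risk** for lobectomy when *any* available predicted
postoperative value (%ppoFEV1, %ppoDLCO, %ppoDLCO') is ≤ 60 %, and **low
risk** when all available values exceed 60 %. Crossing risk class with the
observed respiratory-complication flag gives a 2×2 table, from which the
usual diagnostic metrics (sensitivity, specificity, PPV, NPV) and a
two-sided Fisher exact p-value are computed.

The two-sided Fisher p uses the point-probability convention: with the
table's margins fixed, p is the sum of hypergeometric point probabilities of
all tables at most as likely as the observed one (with a small relative
tolerance for floating-point ties). This matches mainstream statistics
software.

Metrics whose denominator is zero are reported as ``None`` and listed in
``DiagnosticMetrics.undefined`` — never silently set to 0 or NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import hypergeom

from .errors import ParameterError, ValidationError

__all__ = [
    "RiskTable",
    "DiagnosticMetrics",
    "RiskRecord",
    "stratify_risk",
    "contingency_from_cohort",
    "diagnostic_metrics",
    "fisher_exact_two_sided",
]

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class RiskTable:
    """2×2 counts: risk class × postoperative respiratory complication."""

    high_comp: int
    high_none: int
    low_comp: int
    low_none: int

    def __post_init__(self) -> None:
        for name in ("high_comp", "high_none", "low_comp", "low_none"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ParameterError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.high_comp + self.high_none + self.low_comp + self.low_none

    @property
    def n_high(self) -> int:
        return self.high_comp + self.high_none

    @property
    def n_low(self) -> int:
        return self.low_comp + self.low_none

    def as_array(self) -> np.ndarray:
        return np.array([[self.high_comp, self.high_none], [self.low_comp, self.low_none]])


@dataclass
class DiagnosticMetrics:
    """Diagnostic performance of a risk stratification; ``None`` + an entry in
    ``undefined`` marks a metric with a zero denominator."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    fisher_p: float | None
    undefined: tuple[str, ...] = ()

    def rounded(self, ndigits: int = 2) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, ndigits)
        out["fisher_p"] = None if self.fisher_p is None else float(f"{self.fisher_p:.4g}")
        out["undefined"] = list(self.undefined)
        return out


@dataclass
class RiskRecord:
    """Per-patient input to the contingency builder: predicted postoperative
    values per method, and the complication flag."""

    patient_id: str
    ppo_by_method: Mapping[str, Mapping[str, float | None]]
    complication: bool | None


def stratify_risk(
    ppo_values: Mapping[str, float | None], threshold: float = 60.0
) -> str:
    """Classify a patient from the available ppo values.

    ``high`` if any available value is ≤ threshold (inclusive, per the ≤60 %
    rule); ``low`` if all available values exceed it. At least one value must
    be present.
    """
    available = [v for v in ppo_values.values() if v is not None]
    if not available:
        raise ParameterError("risk stratification needs at least one ppo value")
    return "high" if any(v <= threshold for v in available) else "low"


def contingency_from_cohort(
    records: Iterable[RiskRecord], method: str, threshold: float = 60.0
) -> RiskTable:
    """Cross-tabulate risk class (per ``method``) against complications."""
    counts = {("high", True): 0, ("high", False): 0, ("low", True): 0, ("low", False): 0}
    missing: list[str] = []
    for record in records:
        if record.complication is None:
            missing.append(record.patient_id)
            continue
        risk = stratify_risk(record.ppo_by_method[method], threshold=threshold)
        counts[(risk, bool(record.complication))] += 1
    if missing:
        raise ValidationError(f"records missing complication flags: {missing}")
    return RiskTable(
        high_comp=counts[("high", True)],
        high_none=counts[("high", False)],
        low_comp=counts[("low", True)],
        low_none=counts[("low", False)],
    )


def fisher_exact_two_sided(table: RiskTable) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the point probabilities of every table sharing the observed margins
    whose probability is ≤ the observed table's (relative tie tolerance
    1e-12).
    """
    if table.total < 1:
        raise ParameterError("Fisher test needs at least one observation")
    M = table.total
    n_comp = table.high_comp + table.low_comp  # first-column margin
    n_high = table.n_high  # first-row margin
    k_min = max(0, n_comp - (M - n_high))
    k_max = min(n_high, n_comp)
    ks = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(ks, M, n_comp, n_high)
    p_obs = pmf[table.high_comp - k_min]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def diagnostic_metrics(table: RiskTable) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV + Fisher p for a risk table.

    High risk is the "test positive" state; a complication is the "disease
    present" state: TP = high∧complication, TN = low∧no-complication.
    """
    tp, fp = table.high_comp, table.high_none
    fn, tn = table.low_comp, table.low_none
    values = {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }
    fisher_p = fisher_exact_two_sided(table) if table.total >= 1 else None
    undefined = tuple(name for name, v in values.items() if v is None) + (
        ("fisher_p",) if fisher_p is None else ()
    )
    return DiagnosticMetrics(fisher_p=fisher_p, undefined=undefined, **values)
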