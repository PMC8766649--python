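"""Predicted postoperative (ppo) pulmonary-function calculators.

Three methods predict the percent-of-predicted value of a pulmonary-function
measure (``%FEV1``, ``%DLCO``, or ``%DLCO'``, all on the 0–100 scale) after
lobectomy, each as ``preop % × (1 − resected share)`` with a different
estimate of the resected share:

* **Segment counting (SC, Ali's formula)** — the resected share is the count
  of bronchopulmonary segments removed over the 19 segments of both lungs:
  ``ppo = preop × (1 − s / 19)``.
* **Planar** — the segment fraction is computed within the operated side and
  scaled by that side's share of total perfusion measured on planar
  scintigraphy: ``ppo = preop × (1 − f_side × s / S_side)``.
* **SPECT/CT** — the resected lobes' share of total perfusion counts is
  measured directly on the SPECT volume within CT-delineated lobes:
  ``ppo = preop × (1 − f_lobe)``.

All three coincide exactly when perfusion is proportional to segment count
(``f_lobe = s/19`` and ``f_side × s/S_side = s/19``).

No rounding happens inside these functions; round only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .anatomy import DLCO, DLCO_PRIME, FEV1, LEFT_LOBES, RIGHT_LOBES, side_of
from .errors import ParameterError

__all__ = [
    "SegmentTable",
    "DEFAULT_SEGMENT_TABLE",
    "PulmonaryFunctionPanel",
    "PpoResult",
    "METHOD_SC",
    "METHOD_PLANAR",
    "METHOD_SPECTCT",
    "METHODS",
    "segments_for_resection",
    "sc_ppo",
    "planar_ppo",
    "spectct_ppo",
    "predict_all",
]

METHOD_SC = "sc"
METHOD_PLANAR = "planar"
METHOD_SPECTCT = "spectct"
METHODS: tuple[str, ...] = (METHOD_SC, METHOD_PLANAR, METHOD_SPECTCT)

_STANDARD_SEGMENTS = MappingProxyType({"RUL": 3, "RML": 2, "RLL": 5, "LUL": 5, "LLL": 4})


@dataclass(frozen=True)
class SegmentTable:
    """Bronchopulmonary segment counts per lobe.

    The standard anatomy: 10 right segments (3 upper, 2 middle, 5 lower) and
    9 left (5 upper, 4 lower), 19 in total. All anatomical segments are
    counted as functional.
    """

    segments: Mapping[str, int] = field(default_factory=lambda: dict(_STANDARD_SEGMENTS))

    def __post_init__(self) -> None:
        if set(self.segments) != set(_STANDARD_SEGMENTS):
            raise ParameterError(f"segment table must name exactly {tuple(_STANDARD_SEGMENTS)}")
        if any(int(v) < 1 for v in self.segments.values()):
            raise ParameterError("segment counts must be positive integers")
        object.__setattr__(self, "segments", MappingProxyType(dict(self.segments)))

    @property
    def total(self) -> int:
        return sum(self.segments.values())

    def side_total(self, side: str) -> int:
        lobes = RIGHT_LOBES if side == "right" else LEFT_LOBES
        return sum(self.segments[l] for l in lobes)


DEFAULT_SEGMENT_TABLE = SegmentTable()


@dataclass
class PulmonaryFunctionPanel:
    """Preoperative percent-of-predicted values; DLCO' may be missing."""

    fev1: float | None = None
    dlco: float | None = None
    dlco_prime: float | None = None

    def __post_init__(self) -> None:
        for measure, value in self.items():
            if value is not None and not value > 0:
                raise ParameterError(f"preop %{measure} must be > 0, got {value}")

    def items(self) -> list[tuple[str, float | None]]:
        return [(FEV1, self.fev1), (DLCO, self.dlco), (DLCO_PRIME, self.dlco_prime)]

    def get(self, measure: str) -> float | None:
        return dict(self.items())[measure]


@dataclass
class PpoResult:
    """One predicted postoperative value with an echo of its inputs."""

    method: str
    measure: str
    preop_pct: float
    ppo_pct: float
    inputs: dict = field(default_factory=dict)


def segments_for_resection(
    resection: set[str] | frozenset[str],
    table: SegmentTable = DEFAULT_SEGMENT_TABLE,
) -> tuple[int, int, str]:
    """Resolve a resection (set of lobes, one side only) to
    ``(segments_resected, side_segments, side)``.

    Bilobectomy (two lobes of the right lung) is supported; pneumonectomy and
    resections spanning both sides are not.
    """
    resection = frozenset(resection)
    if not resection:
        raise ParameterError("resection must name at least one lobe")
    unknown = resection - (RIGHT_LOBES | LEFT_LOBES)
    if unknown:
        raise ParameterError(f"unknown lobes in resection: {sorted(unknown)}")
    sides = {side_of(l) for l in resection}
    if len(sides) != 1:
        raise ParameterError("resection spans both lungs; only one-sided resections are supported")
    side = sides.pop()
    s = sum(table.segments[l] for l in resection)
    return s, table.side_total(side), side


def sc_ppo(preop_pct: float, s: int, total: int = 19) -> float:
    """Segment-counting prediction: ``preop × (1 − s/total)``."""
    if not preop_pct > 0:
        raise ParameterError(f"preop_pct must be > 0, got {preop_pct}")
    if not 0 <= s <= total:
        raise ParameterError(f"segments resected must be in [0, {total}], got {s}")
    return preop_pct * (1.0 - s / total)


def planar_ppo(preop_pct: float, f_side: float, s: int, s_side: int) -> float:
    """Planar-scintigraphy prediction: ``preop × (1 − f_side × s/S_side)``."""
    if not preop_pct > 0:
        raise ParameterError(f"preop_pct must be > 0, got {preop_pct}")
    if not 0 <= f_side <= 1:
        raise ParameterError(f"f_side must be in [0, 1], got {f_side}")
    if not 0 <= s <= s_side:
        raise ParameterError(f"segments resected must be in [0, {s_side}], got {s}")
    return preop_pct * (1.0 - f_side * s / s_side)


def spectct_ppo(preop_pct: float, f_lobe: float) -> float:
    """SPECT/CT prediction: ``preop × (1 − f_lobe)``."""
    if not preop_pct > 0:
        raise ParameterError(f"preop_pct must be > 0, got {preop_pct}")
    if not 0 <= f_lobe <= 1:
        raise ParameterError(f"f_lobe must be in [0, 1], got {f_lobe}")
    return preop_pct * (1.0 - f_lobe)


def predict_all(
    panel: PulmonaryFunctionPanel,
    resection: set[str] | frozenset[str],
    f_side: float,
    f_lobe: float,
    table: SegmentTable = DEFAULT_SEGMENT_TABLE,
) -> list[PpoResult]:
    """All three methods for every available measure.

    Missing measures (typically DLCO') yield no result rather than an error,
    so a panel without DLCO' produces 6 results instead of 9.
    """
    s, s_side, side = segments_for_resection(resection, table)
    results: list[PpoResult] = []
    for measure, preop in panel.items():
        if preop is None:
            continue
        common = {"s": s, "s_side": s_side, "side": side}
        results.append(
            PpoResult(METHOD_SC, measure, preop, sc_ppo(preop, s, table.total), dict(common))
        )
        results.append(
            PpoResult(
                METHOD_PLANAR,
                measure,
                preop,
                planar_ppo(preop, f_side, s, s_side),
                {**common, "f_side": f_side},
            )
        )
        results.append(
            PpoResult(
                METHOD_SPECTCT,
                measure,
                preop,
                spectct_ppo(preop, f_lobe),
                {**common, "f_lobe": f_lobe},
            )
        )
    return results
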