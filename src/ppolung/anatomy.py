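"""Lobe naming, integer labels, and pulmonary-function measure constants."""

from __future__ import annotations

__all__ = [
    "LOBES",
    "LOBE_LABELS",
    "LABEL_LOBES",
    "RIGHT_LOBES",
    "LEFT_LOBES",
    "MEASURES",
    "FEV1",
    "DLCO",
    "DLCO_PRIME",
    "side_of",
]

# Integer labels used in LobeLabelMap volumes (0 = background).
LOBE_LABELS: dict[str, int] = {"RUL": 1, "RML": 2, "RLL": 3, "LUL": 4, "LLL": 5}
LABEL_LOBES: dict[int, str] = {v: k for k, v in LOBE_LABELS.items()}
LOBES: tuple[str, ...] = ("RUL", "RML", "RLL", "LUL", "LLL")

RIGHT_LOBES: frozenset[str] = frozenset({"RUL", "RML", "RLL"})
LEFT_LOBES: frozenset[str] = frozenset({"LUL", "LLL"})

# Pulmonary-function measures. DLCO' differs from DLCO only in how alveolar
# volume is determined (single-breath helium dilution); DLCO' records may be
# missing in a cohort.
FEV1 = "fev1"
DLCO = "dlco"
DLCO_PRIME = "dlco_prime"
MEASURES: tuple[str, ...] = (FEV1, DLCO, DLCO_PRIME)


def side_of(lobe: str) -> str:
    """Return ``'right'`` or ``'left'`` for a lobe code."""
    if lobe in RIGHT_LOBES:
        return "right"
    if lobe in LEFT_LOBES:
        return "left"
    raise KeyError(f"unknown lobe {lobe!r}")
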