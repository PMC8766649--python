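"""Simulated lobectomy cohorts.

Each simulated patient carries a true lobar perfusion distribution, a sampled
resection, preoperative percent-of-predicted pulmonary-function values, noisy
imaging-derived perfusion-fraction estimates, a true predicted-postoperative
value per measure (defined by the SPECT/CT formula on the *true* lobar
fraction), an observed postoperative value (true ppo plus Gaussian
measurement/recovery noise), and a respiratory-complication flag drawn with a
rate set by the patient's true risk group (any true ppo ≤ 60% → high risk).

Defaults emulate a 30-patient lobectomy series: the resection mix follows the
study procedure frequencies (6 RUL, 5 RML, 8 RLL, 1 RUL+RML, 1 RML+RLL,
5 LUL, 4 LLL), complication rates default to 42.9 % (high risk) and 8.7 %
(low risk), and DLCO' is occasionally missing, mirroring a cohort where one
patient lacked a single-breath measurement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import DLCO, DLCO_PRIME, FEV1, LEFT_LOBES, LOBES, MEASURES, RIGHT_LOBES
from .errors import ParameterError, ValidationError
from .phantom import PHYSIOLOGIC_FLOW_FRACTIONS
from .ppo import spectct_ppo
from .risk import stratify_risk

__all__ = [
    "CohortSimParams",
    "CohortRecord",
    "DEFAULT_RESECTION_WEIGHTS",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "cohort_to_dataframe",
]

# Procedure mix of a representative lobectomy series (counts out of 30).
DEFAULT_RESECTION_WEIGHTS: dict[frozenset, float] = {
    frozenset({"RUL"}): 6,
    frozenset({"RML"}): 5,
    frozenset({"RLL"}): 8,
    frozenset({"RUL", "RML"}): 1,
    frozenset({"RML", "RLL"}): 1,
    frozenset({"LUL"}): 5,
    frozenset({"LLL"}): 4,
}


@dataclass
class CohortSimParams:
    """Parameters of the cohort simulator.

    Percent values are on the 0–100 scale; fraction noise is on the 0–1
    perfusion-fraction scale. ``lobar_fraction_alpha`` scales the Dirichlet
    concentration around the physiologic lobar flow shares (larger → less
    between-patient variation).
    """

    n_patients: int = 30
    preop_means: dict[str, float] = field(
        default_factory=lambda: {FEV1: 95.0, DLCO: 98.0, DLCO_PRIME: 95.0}
    )
    preop_sds: dict[str, float] = field(
        default_factory=lambda: {FEV1: 15.0, DLCO: 15.0, DLCO_PRIME: 15.0}
    )
    preop_correlation: float = 0.85
    fraction_noise_sd: float = 0.02
    postop_noise_sd: float = 8.0
    complication_rate_high: float = 3 / 7
    complication_rate_low: float = 2 / 23
    missing_dlco_prime_rate: float = 1 / 30
    fev1_fvc_mean: float = 72.0
    fev1_fvc_sd: float = 9.0
    lobar_fraction_alpha: float = 60.0
    resection_weights: dict[frozenset, float] = field(
        default_factory=lambda: dict(DEFAULT_RESECTION_WEIGHTS)
    )
    risk_threshold_pct: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        for name in ("complication_rate_high", "complication_rate_low", "missing_dlco_prime_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ParameterError(f"{name} must be in [0, 1], got {rate}")
        for name in ("fraction_noise_sd", "postop_noise_sd", "fev1_fvc_sd"):
            sd = getattr(self, name)
            if sd < 0:
                raise ParameterError(f"{name} must be >= 0, got {sd}")
        for measure in MEASURES:
            if self.preop_sds.get(measure, 0.0) < 0:
                raise ParameterError("preop sds must be >= 0")
            if not self.preop_means.get(measure, 1.0) > 0:
                raise ParameterError("preop means must be > 0")
        if not 0 <= self.preop_correlation <= 1:
            raise ParameterError("preop_correlation must be in [0, 1]")
        if not self.lobar_fraction_alpha > 0:
            raise ParameterError("lobar_fraction_alpha must be > 0")
        for resection, w in self.resection_weights.items():
            if w < 0:
                raise ParameterError("resection weights must be >= 0")
            if not (resection <= RIGHT_LOBES or resection <= LEFT_LOBES):
                raise ParameterError(f"resection {set(resection)} spans both lungs")
        if sum(self.resection_weights.values()) <= 0:
            raise ParameterError("resection weights must not all be zero")


@dataclass
class CohortRecord:
    """One simulated (or loaded) patient."""

    patient_id: str
    resection: frozenset
    fev1_fvc: float | None
    preop: dict[str, float | None]  # measure -> % predicted
    true_lobar_fractions: dict[str, float] | None
    f_lobe_true: float | None
    f_side_true: float | None
    f_lobe_spect: float | None  # SPECT/CT estimate of the resected-lobe fraction
    f_side_planar: float | None  # planar estimate of the resected-side fraction
    postop: dict[str, float | None]  # measure -> observed postoperative %
    complication: bool | None
    risk_true: str | None = None


def _clip_pct(value: float, lo: float = 20.0) -> float:
    """Floor % values; keeps pathological tail draws physiologically plausible."""
    return max(float(value), lo)


def simulate_cohort(params: CohortSimParams, segment_table=None) -> list[CohortRecord]:
    """Draw a synthetic cohort; deterministic for a fixed ``params.seed``.

    ``segment_table`` is accepted for signature symmetry with the predictors
    but the simulator itself only needs lobar flow, so it may be None.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    resections = list(params.resection_weights)
    weights = np.array([params.resection_weights[r] for r in resections], dtype=float)
    weights /= weights.sum()
    base = np.array([PHYSIOLOGIC_FLOW_FRACTIONS[l] for l in LOBES])

    records: list[CohortRecord] = []
    for i in range(params.n_patients):
        resection = resections[int(rng.choice(len(resections), p=weights))]
        fracs = rng.dirichlet(params.lobar_fraction_alpha * base)
        lobar = {lobe: float(f) for lobe, f in zip(LOBES, fracs)}
        f_lobe_true = sum(lobar[l] for l in resection)
        side_lobes = RIGHT_LOBES if resection <= RIGHT_LOBES else LEFT_LOBES
        f_side_true = sum(lobar[l] for l in side_lobes)

        f_lobe_spect = float(np.clip(f_lobe_true + rng.normal(0.0, params.fraction_noise_sd), 0.0, 1.0))
        f_side_planar = float(np.clip(f_side_true + rng.normal(0.0, params.fraction_noise_sd), 0.0, 1.0))

        # within-patient correlation of FEV1/DLCO/DLCO' via a shared latent
        # function level (spirometric and diffusion impairment travel together)
        rho = params.preop_correlation
        level = float(rng.normal())
        preop: dict[str, float | None] = {}
        for measure in MEASURES:
            z = rho * level + math.sqrt(1.0 - rho * rho) * float(rng.normal())
            preop[measure] = _clip_pct(
                params.preop_means[measure] + params.preop_sds[measure] * z
            )
        has_dlco_prime = rng.random() >= params.missing_dlco_prime_rate
        if not has_dlco_prime:
            preop[DLCO_PRIME] = None
        fev1_fvc = float(np.clip(rng.normal(params.fev1_fvc_mean, params.fev1_fvc_sd), 35.0, 95.0))

        true_ppo = {
            m: (spectct_ppo(v, f_lobe_true) if v is not None else None) for m, v in preop.items()
        }
        risk = stratify_risk(true_ppo, threshold=params.risk_threshold_pct)
        rate = params.complication_rate_high if risk == "high" else params.complication_rate_low
        complication = bool(rng.random() < rate)

        postop: dict[str, float | None] = {}
        for measure in MEASURES:
            if true_ppo[measure] is None:
                postop[measure] = None
            elif params.postop_noise_sd == 0:
                postop[measure] = true_ppo[measure]
            else:
                postop[measure] = max(
                    1.0, float(true_ppo[measure] + rng.normal(0.0, params.postop_noise_sd))
                )

        records.append(
            CohortRecord(
                patient_id=f"P{i + 1:04d}",
                resection=resection,
                fev1_fvc=fev1_fvc,
                preop=preop,
                true_lobar_fractions=lobar,
                f_lobe_true=float(f_lobe_true),
                f_side_true=float(f_side_true),
                f_lobe_spect=f_lobe_spect,
                f_side_planar=f_side_planar,
                postop=postop,
                complication=complication,
                risk_true=risk,
            )
        )
    return records


# --------------------------------------------------------------------------
# CSV round-trip
# --------------------------------------------------------------------------

_REQUIRED_COLUMNS = [
    "patient_id",
    "resection",
    "preop_fev1",
    "preop_dlco",
    "preop_dlco_prime",
    "postop_fev1",
    "postop_dlco",
    "postop_dlco_prime",
    "complication",
]
_OPTIONAL_COLUMNS = (
    ["fev1_fvc", "f_lobe_true", "f_side_true", "f_lobe_spect", "f_side_planar", "risk_true"]
    + [f"frac_{l}" for l in LOBES]
)


def cohort_to_dataframe(records: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "patient_id": r.patient_id,
            "resection": "+".join(sorted(r.resection)),
            "fev1_fvc": r.fev1_fvc,
            "preop_fev1": r.preop.get(FEV1),
            "preop_dlco": r.preop.get(DLCO),
            "preop_dlco_prime": r.preop.get(DLCO_PRIME),
            "f_lobe_true": r.f_lobe_true,
            "f_side_true": r.f_side_true,
            "f_lobe_spect": r.f_lobe_spect,
            "f_side_planar": r.f_side_planar,
            "postop_fev1": r.postop.get(FEV1),
            "postop_dlco": r.postop.get(DLCO),
            "postop_dlco_prime": r.postop.get(DLCO_PRIME),
            "complication": None if r.complication is None else int(r.complication),
            "risk_true": r.risk_true,
        }
        for lobe in LOBES:
            row[f"frac_{lobe}"] = (
                None if r.true_lobar_fractions is None else r.true_lobar_fractions.get(lobe)
            )
        rows.append(row)
    columns = [
        "patient_id",
        "resection",
        "fev1_fvc",
        "preop_fev1",
        "preop_dlco",
        "preop_dlco_prime",
        "f_lobe_true",
        "f_side_true",
        "f_lobe_spect",
        "f_side_planar",
        "postop_fev1",
        "postop_dlco",
        "postop_dlco_prime",
        "complication",
        "risk_true",
    ] + [f"frac_{l}" for l in LOBES]
    return pd.DataFrame(rows, columns=columns)


def write_cohort(records: list[CohortRecord], path) -> None:
    """Write a cohort CSV; missing values become empty cells.

    Floats use %.17g so a write/read cycle is lossless.
    """
    cohort_to_dataframe(records).to_csv(path, index=False, float_format="%.17g")


def _cell(value, line_no: int, column: str, numeric: bool = True):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    if not numeric:
        return str(value)
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"line {line_no}: column {column!r} is not numeric: {value!r}") from exc


def read_cohort(path) -> list[CohortRecord]:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-made with the
    same schema). Malformed rows are reported with their line numbers."""
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "resection": str, "risk_true": str},
        float_precision="round_trip",
    )
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing required columns: {missing}")
    if df.empty:
        logging.getLogger("ppolung").warning("cohort file %s contains no records", path)
    records: list[CohortRecord] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        resection_str = row["resection"]
        if not isinstance(resection_str, str) or not resection_str:
            raise ValidationError(f"line {line_no}: empty resection")
        resection = frozenset(resection_str.split("+"))
        bad = resection - (RIGHT_LOBES | LEFT_LOBES)
        if bad:
            raise ValidationError(f"line {line_no}: unknown lobes {sorted(bad)} in resection")
        comp = _cell(row.get("complication"), line_no, "complication")
        if comp is not None and comp not in (0.0, 1.0):
            raise ValidationError(f"line {line_no}: complication must be 0 or 1, got {comp}")
        lobar = {l: _cell(row.get(f"frac_{l}"), line_no, f"frac_{l}") for l in LOBES}
        if all(v is None for v in lobar.values()):
            lobar = None
        risk = row.get("risk_true")
        records.append(
            CohortRecord(
                patient_id=str(row["patient_id"]),
                resection=resection,
                fev1_fvc=_cell(row.get("fev1_fvc"), line_no, "fev1_fvc"),
                preop={
                    FEV1: _cell(row.get("preop_fev1"), line_no, "preop_fev1"),
                    DLCO: _cell(row.get("preop_dlco"), line_no, "preop_dlco"),
                    DLCO_PRIME: _cell(row.get("preop_dlco_prime"), line_no, "preop_dlco_prime"),
                },
                true_lobar_fractions=lobar,
                f_lobe_true=_cell(row.get("f_lobe_true"), line_no, "f_lobe_true"),
                f_side_true=_cell(row.get("f_side_true"), line_no, "f_side_true"),
                f_lobe_spect=_cell(row.get("f_lobe_spect"), line_no, "f_lobe_spect"),
                f_side_planar=_cell(row.get("f_side_planar"), line_no, "f_side_planar"),
                postop={
                    FEV1: _cell(row.get("postop_fev1"), line_no, "postop_fev1"),
                    DLCO: _cell(row.get("postop_dlco"), line_no, "postop_dlco"),
                    DLCO_PRIME: _cell(row.get("postop_dlco_prime"), line_no, "postop_dlco_prime"),
                },
                complication=None if comp is None else bool(comp),
                risk_true=None if not isinstance(risk, str) or risk == "" else risk,
            )
        )
    return records
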