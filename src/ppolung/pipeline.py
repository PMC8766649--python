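"""End-to-end orchestration: simulate → segment → quantify → predict →
compare → risk-stratify, with all file I/O.

The pipeline writes one run directory containing NIfTI volumes, the trace
and cohort CSVs, JSON reports (perfusion fractions, agreement statistics per
method and measure, risk tables with diagnostic metrics), a human-readable
summary, and a manifest. CSV/JSON outputs are byte-identical across runs
with the same configuration and seed.

Seeding: the run seed drives the phantom directly; the cohort simulator uses
``seed + 1000`` so the two stages draw from independent streams.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from .anatomy import MEASURES
from .cohort import (
    CohortRecord,
    CohortSimParams,
    read_cohort,
    simulate_cohort,
    write_cohort,
)
from .errors import ParameterError, ValidationError
from .lungseg import (
    DEFAULT_CLOSING_RADIUS,
    DEFAULT_CT_THRESHOLD,
    binarize_ct,
    close_mask,
    extract_lung_field,
    lobe_volume_report,
    split_lobes,
)
from .perfquant import (
    lobar_fractions,
    planar_side_fraction,
    side_fractions,
    side_rois_from_labels,
)
from .phantom import PhantomConfig, generate_thorax_phantom, project_planar
from .ppo import METHODS, PulmonaryFunctionPanel, predict_all
from .risk import RiskRecord, contingency_from_cohort, diagnostic_metrics
from .traces import FissureTraceSet
from .volume import VoxelVolume

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

logger = logging.getLogger("ppolung")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str | Path = "ppolung_run"
    seed: int = 0
    binarize_threshold: float = DEFAULT_CT_THRESHOLD
    closing_radius: int = DEFAULT_CLOSING_RADIUS
    risk_threshold: float = 60.0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    cohort: CohortSimParams = field(default_factory=CohortSimParams)
    # optional external inputs; when set they replace the simulation stage
    ct_path: str | None = None
    spect_path: str | None = None
    traces_path: str | None = None
    cohort_path: str | None = None

    def validate(self) -> None:
        if int(self.seed) != self.seed:
            raise ParameterError("seed must be an integer")
        for name in ("binarize_threshold", "risk_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")
        for name in ("ct_path", "spect_path", "traces_path", "cohort_path"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ParameterError(f"{name} does not exist: {path}")


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from a TOML key-value file.

    Top-level keys map to RunConfig fields; ``[phantom]`` and ``[cohort]``
    tables map to the respective parameter sets.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    phantom_kwargs = raw.pop("phantom", {})
    cohort_kwargs = raw.pop("cohort", {})
    if "grid_shape" in phantom_kwargs:
        phantom_kwargs["grid_shape"] = tuple(phantom_kwargs["grid_shape"])
    if "dropout_lesions" in phantom_kwargs:
        phantom_kwargs["dropout_lesions"] = tuple(
            (tuple(c), r, s) for c, r, s in phantom_kwargs["dropout_lesions"]
        )
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(
        phantom=PhantomConfig(**phantom_kwargs),
        cohort=CohortSimParams(**cohort_kwargs),
        **raw,
    )


def _round_floats(obj, ndigits: int = 10):
    """Round floats for stable, readable JSON (p-values keep 4 sig digits
    at the reporting layer; everything else gets a fixed decimal cap)."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(_round_floats(payload), indent=2, sort_keys=True) + "\n")


def _agreement_block(x, y) -> dict | None:
    xc, yc = agr.pairwise_complete(x, y)
    if len(xc) < 3:
        return None
    ba = agr.bland_altman(xc, yc)
    r, p = agr.pearson_correlation(xc, yc)
    slope, intercept, r2 = agr.regression_r2(xc, yc)
    ad = agr.absolute_differences(xc, yc)
    return {
        "n": ba.n,
        "pearson_r": r,
        "pearson_p": float(f"{p:.4g}"),
        "slope": slope,
        "intercept": intercept,
        "r2": r2,
        "bland_altman": {
            "mean_difference": ba.mean_difference,
            "sd_difference": ba.sd_difference,
            "se_mean": ba.se_mean,
            "lower_loa": ba.lower_loa,
            "upper_loa": ba.upper_loa,
        },
        "abs_differences": {
            "mean": ad.mean,
            "sd": ad.sd,
            "max": ad.max,
            "min": ad.min,
        },
    }


def predict_cohort(records: list[CohortRecord]) -> pd.DataFrame:
    """Predicted postoperative values for every record, method, and measure."""
    rows = []
    for r in records:
        if r.f_side_planar is None or r.f_lobe_spect is None:
            raise ValidationError(f"record {r.patient_id} lacks perfusion fractions")
        panel = PulmonaryFunctionPanel(
            fev1=r.preop.get("fev1"),
            dlco=r.preop.get("dlco"),
            dlco_prime=r.preop.get("dlco_prime"),
        )
        for res in predict_all(panel, r.resection, r.f_side_planar, r.f_lobe_spect):
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "method": res.method,
                    "measure": res.measure,
                    "preop_pct": res.preop_pct,
                    "ppo_pct": res.ppo_pct,
                    "s": res.inputs.get("s"),
                    "s_side": res.inputs.get("s_side"),
                    "f_side": res.inputs.get("f_side"),
                    "f_lobe": res.inputs.get("f_lobe"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "method", "measure", "preop_pct", "ppo_pct",
            "s", "s_side", "f_side", "f_lobe",
        ],
    )


def compare_cohort(records: list[CohortRecord], ppo_df: pd.DataFrame) -> dict:
    """Agreement statistics (all patients + impaired subgroups) per method
    and measure, predicted vs observed postoperative values."""
    postop = {
        (r.patient_id, m): r.postop.get(m) for r in records for m in MEASURES
    }
    report: dict = {"all": {}, "subgroups": {}}
    def block_for(subset_ids, method, measure):
        sub = ppo_df[(ppo_df.method == method) & (ppo_df.measure == measure)]
        sub = sub[sub.patient_id.isin(subset_ids)]
        x = sub.ppo_pct.tolist()
        y = [postop[(pid, measure)] for pid in sub.patient_id]
        return _agreement_block(x, y)

    all_ids = {r.patient_id for r in records}
    for method in METHODS:
        report["all"][method] = {}
        for measure in MEASURES:
            block = block_for(all_ids, method, measure)
            if block is not None:
                report["all"][method][measure] = block
    for criterion in agr.SUBGROUP_CRITERIA:
        subset = agr.subgroup_filter(records, criterion)
        ids = {r.patient_id for r in subset}
        crit_block: dict = {"n_records": len(subset)}
        for method in METHODS:
            crit_block[method] = {}
            for measure in MEASURES:
                block = block_for(ids, method, measure)
                if block is not None:
                    crit_block[method][measure] = block
        report["subgroups"][criterion] = crit_block
    return report


def risk_report(records: list[CohortRecord], ppo_df: pd.DataFrame, threshold: float = 60.0) -> dict:
    """Risk tables and diagnostic metrics per prediction method."""
    ppo_map: dict[str, dict[str, dict[str, float | None]]] = {}
    for row in ppo_df.itertuples():
        ppo_map.setdefault(row.patient_id, {m: {} for m in METHODS})
        ppo_map[row.patient_id][row.method][row.measure] = row.ppo_pct
    risk_records = [
        RiskRecord(
            patient_id=r.patient_id,
            ppo_by_method=ppo_map.get(r.patient_id, {m: {} for m in METHODS}),
            complication=r.complication,
        )
        for r in records
    ]
    out: dict = {"threshold_pct": threshold}
    for method in METHODS:
        table = contingency_from_cohort(risk_records, method, threshold=threshold)
        metrics = diagnostic_metrics(table)
        out[method] = {
            "table": {
                "high_comp": table.high_comp,
                "high_none": table.high_none,
                "low_comp": table.low_comp,
                "low_none": table.low_none,
            },
            "metrics": metrics.rounded(),
        }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns it as a dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_files: list[str] = []
    bundle: dict = {}

    def _stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    # --- simulate / load imaging -------------------------------------------
    t0 = _stage("simulate")
    truth = None
    if config.ct_path and config.spect_path:
        ct = VoxelVolume.load_nifti(config.ct_path)
        spect = VoxelVolume.load_nifti(config.spect_path)
        traces = FissureTraceSet.from_csv(config.traces_path)
    else:
        phantom_cfg = config.phantom
        phantom_cfg.seed = int(config.seed)
        ct, spect, truth = generate_thorax_phantom(phantom_cfg)
        traces = truth.fissure_traces
        ct.save_nifti(out / "ct.nii.gz")
        spect.save_nifti(out / "spect.nii.gz")
        VoxelVolume(truth.lobe_labels, ct.spacing_mm).save_nifti(out / "labels_truth.nii.gz")
        traces.to_csv(out / "traces.csv")
        manifest_files += ["ct.nii.gz", "spect.nii.gz", "labels_truth.nii.gz", "traces.csv"]
    logger.info("simulate done in %.2fs", time.perf_counter() - t0)

    # --- segment ------------------------------------------------------------
    t0 = _stage("segment")
    mask = binarize_ct(ct, config.binarize_threshold)
    closed = close_mask(mask, config.closing_radius)
    lung_field = extract_lung_field(closed)
    labels = split_lobes(lung_field, traces)
    VoxelVolume(labels, ct.spacing_mm).save_nifti(out / "labels.nii.gz")
    lobe_volume_report(labels, ct.spacing_mm).to_csv(out / "lobe_volumes.csv", index=False)
    manifest_files += ["labels.nii.gz", "lobe_volumes.csv"]
    logger.info("segment done in %.2fs", time.perf_counter() - t0)

    # --- quantify -----------------------------------------------------------
    t0 = _stage("quantify")
    perf = lobar_fractions(spect, labels)
    anterior = project_planar(spect, "anterior")
    posterior = project_planar(spect, "posterior")
    left_roi, right_roi = side_rois_from_labels(labels)
    planar = planar_side_fraction(anterior, posterior, left_roi, right_roi)
    fractions_payload = {
        "lobar_fractions": perf.fractions,
        "lobar_counts": perf.counts,
        "side_fractions_volumetric": side_fractions(perf),
        "side_fractions_planar": planar,
    }
    if truth is not None:
        fractions_payload["lobar_fractions_truth"] = truth.lobar_perfusion_fractions
    _write_json(fractions_payload, out / "fractions.json")
    manifest_files.append("fractions.json")
    bundle["fractions"] = fractions_payload
    logger.info("quantify done in %.2fs", time.perf_counter() - t0)

    # --- cohort -------------------------------------------------------------
    t0 = _stage("cohort")
    if config.cohort_path:
        records = read_cohort(config.cohort_path)
        if not records:
            logger.warning("cohort file %s contains no records", config.cohort_path)
    else:
        cohort_cfg = config.cohort
        cohort_cfg.seed = int(config.seed) + 1000
        records = simulate_cohort(cohort_cfg)
    write_cohort(records, out / "cohort.csv")
    manifest_files.append("cohort.csv")

    ppo_df = predict_cohort(records)
    ppo_df.to_csv(out / "ppo.csv", index=False)
    manifest_files.append("ppo.csv")
    bundle["ppo"] = ppo_df
    logger.info("cohort+predict done in %.2fs", time.perf_counter() - t0)

    # --- compare + risk -----------------------------------------------------
    t0 = _stage("compare")
    agreement_payload = compare_cohort(records, ppo_df)
    _write_json(agreement_payload, out / "agreement.json")
    manifest_files.append("agreement.json")
    bundle["agreement"] = agreement_payload

    risk_payload = risk_report(records, ppo_df, config.risk_threshold)
    _write_json(risk_payload, out / "risk.json")
    manifest_files.append("risk.json")
    bundle["risk"] = risk_payload
    logger.info("compare+risk done in %.2fs", time.perf_counter() - t0)

    # --- summary + manifest --------------------------------------------------
    lines = ["ppolung run summary", "===================", f"seed: {config.seed}", ""]
    lines.append("lobar perfusion fractions (measured):")
    for lobe, f in perf.fractions.items():
        lines.append(f"  {lobe}: {f:.4f}")
    lines.append("")
    lines.append(f"cohort: {len(records)} records")
    for method in METHODS:
        block = agreement_payload["all"].get(method, {}).get("fev1")
        if block:
            ba = block["bland_altman"]
            lines.append(
                f"  {method:8s} FEV1: r={block['pearson_r']:.3f}, "
                f"mean diff={ba['mean_difference']:+.1f}%, "
                f"LoA [{ba['lower_loa']:.1f}, {ba['upper_loa']:.1f}]"
            )
    for method in METHODS:
        m = risk_payload[method]["metrics"]
        t = risk_payload[method]["table"]
        lines.append(
            f"  {method:8s} risk: high {t['high_comp']}/{t['high_comp'] + t['high_none']}, "
            f"low {t['low_comp']}/{t['low_comp'] + t['low_none']}, "
            f"sens={m['sensitivity']}, spec={m['specificity']}, fisher p={m['fisher_p']}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    manifest_files.append("summary.txt")

    manifest = {"files": sorted(manifest_files), "seed": config.seed}
    _write_json(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
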