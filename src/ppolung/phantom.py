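"""Digital thorax phantom with known lobar perfusion truth.

The phantom emulates a perfusion SPECT/CT study of the kind used to plan
lobectomy: a CT-like attenuation volume (air −1000, lung parenchyma −800,
soft tissue +40 on an HU-like scale), and a co-registered SPECT-like
perfusion-count volume rendered from a known lobar blood-flow distribution.

Geometry: two ellipsoidal lungs inside an ellipsoidal thorax. The left lung
is split into two lobes by one oblique plane; the right lung into three by an
oblique plane plus a second ("horizontal") plane that carves the
anterior-inferior middle lobe — the simplest geometry with the clinical
2-lobe/3-lobe asymmetry and a small, awkward right middle lobe.

Perfusion: each lobe receives a configurable fraction of total blood flow
(defaults are physiologic), uniformly distributed within the lobe, then
modulated by a supine gravity gradient (dorsal flow > ventral flow) and by
optional spherical "dropout" defects emulating emphysematous destruction.
The ground-truth lobar fractions are recomputed by voxel-wise integration of
the final density, so they remain exact whatever modifiers are applied.

SPECT rendering: the true density is convolved with an isotropic Gaussian
point-spread function (default FWHM 3.9 mm, matching a reconstructed and
post-filtered acquisition at 3.9 mm voxels), scaled to the expected total
count level, and Poisson sampled. Attenuation and scatter are not simulated:
the volumes stand for attenuation-corrected reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .anatomy import LOBE_LABELS, LOBES
from .errors import ParameterError
from .traces import FissureTraceSet, TracePolyline
from .volume import VoxelVolume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_thorax_phantom",
    "project_planar",
    "perturbed_traces",
    "HU_AIR",
    "HU_LUNG",
    "HU_SOFT_TISSUE",
    "PHYSIOLOGIC_FLOW_FRACTIONS",
]

HU_AIR = -1000.0
HU_LUNG = -800.0
HU_SOFT_TISSUE = 40.0

# Default per-lobe share of pulmonary blood flow (sums to 1). Approximate
# physiologic values: lower lobes dominate, the right middle lobe is small.
PHYSIOLOGIC_FLOW_FRACTIONS: dict[str, float] = {
    "RUL": 0.18,
    "RML": 0.08,
    "RLL": 0.25,
    "LUL": 0.22,
    "LLL": 0.27,
}


@dataclass
class PhantomConfig:
    """Parameters of one synthetic thorax study.

    Parameters
    ----------
    grid_shape:
        Voxels per (z, y, x) axis; each axis must be >= 32 so the two lung
        ellipsoids fit with clearance from the volume border.
    voxel_size_mm:
        Isotropic voxel spacing. Default 3.9 mm (reconstructed SPECT matrix).
    psf_fwhm_mm:
        Full width at half maximum of the Gaussian post-filter PSF applied to
        the perfusion density before counting. Default 3.9 mm.
    total_counts:
        Expected total SPECT counts over the volume (Poisson mean).
    gravity_gradient:
        Multiplicative ventral→dorsal perfusion slope in [0, 1): a voxel at
        the most dorsal position receives ``(1 + gravity_gradient)`` times the
        flow of a ventral voxel, emulating supine injection.
    dropout_lesions:
        Sequence of ``((z, y, x), radius_voxels, perfusion_scale)`` spherical
        defects; density inside each sphere is multiplied by
        ``perfusion_scale`` in [0, 1].
    lobar_flow_fractions:
        True per-lobe flow shares before gradient/lesions; must sum to 1.
    vessels:
        Embed one soft-tissue vessel tube per lung in the CT volume (the
        defect the morphological closing step repairs). Perfusion is
        unaffected.
    trace_slice_step:
        Emit ground-truth fissure traces on every n-th axial slice.
    seed:
        RNG seed for the Poisson count sampling.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 3.9
    psf_fwhm_mm: float = 3.9
    total_counts: float = 2.0e6
    gravity_gradient: float = 0.3
    dropout_lesions: tuple = ()
    lobar_flow_fractions: dict[str, float] = field(
        default_factory=lambda: dict(PHYSIOLOGIC_FLOW_FRACTIONS)
    )
    vessels: bool = True
    trace_slice_step: int = 2
    seed: int = 0

    def validate(self) -> None:
        shape = tuple(int(n) for n in self.grid_shape)
        if len(shape) != 3 or any(n < 32 for n in shape):
            raise ParameterError(
                f"grid_shape must be 3 axes of >=32 voxels to fit two lungs, got {self.grid_shape}"
            )
        if not self.voxel_size_mm > 0:
            raise ParameterError("voxel_size_mm must be > 0")
        if not self.total_counts > 0:
            raise ParameterError("total_counts must be > 0")
        if not self.psf_fwhm_mm >= 0:
            raise ParameterError("psf_fwhm_mm must be >= 0")
        if not 0 <= self.gravity_gradient < 1:
            raise ParameterError("gravity_gradient must be in [0, 1)")
        if self.trace_slice_step < 1:
            raise ParameterError("trace_slice_step must be >= 1")
        for lesion in self.dropout_lesions:
            center, radius, scale = lesion
            if len(tuple(center)) != 3:
                raise ParameterError(f"lesion center must be (z, y, x), got {center!r}")
            if not radius > 0:
                raise ParameterError(f"lesion radius must be > 0, got {radius!r}")
            if not 0 <= scale <= 1:
                raise ParameterError(f"lesion perfusion_scale must be in [0, 1], got {scale!r}")
        fracs = self.lobar_flow_fractions
        if set(fracs) != set(LOBES):
            raise ParameterError(f"lobar_flow_fractions must name exactly {LOBES}")
        if any(f < 0 for f in fracs.values()) or abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ParameterError("lobar_flow_fractions must be nonnegative and sum to 1")


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom (for recovery tests)."""

    lobe_labels: np.ndarray  # int16 (z, y, x); 0 background, 1..5 per LOBE_LABELS
    lobar_perfusion_fractions: dict[str, float]
    fissure_traces: FissureTraceSet
    density: np.ndarray  # noise-free perfusion density, normalised to sum 1
    spacing_mm: tuple[float, float, float]

    @property
    def lung_field(self) -> np.ndarray:
        return (self.lobe_labels > 0).astype(np.uint8)

    def side_fractions(self) -> dict[str, float]:
        right = sum(self.lobar_perfusion_fractions[l] for l in ("RUL", "RML", "RLL"))
        left = sum(self.lobar_perfusion_fractions[l] for l in ("LUL", "LLL"))
        return {"right": right, "left": left}


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------


@dataclass
class _Geometry:
    body: np.ndarray
    labels: np.ndarray
    lung_params: dict[str, dict]  # per side: center, semiaxes, boundary line coefficients


def _boundary_y(cy: float, ay: float, az: float, cz: float, z: np.ndarray, kind: str) -> np.ndarray:
    """Boundary surface height y(z) for a fissure, linear in the normalised
    apex→base coordinate u in [0, 1]."""
    u = (np.asarray(z, dtype=float) - (cz - az)) / (2 * az)
    if kind == "oblique":
        # posterior-superior to anterior-inferior, the classic oblique course
        return cy + ay * (0.6 - 1.2 * u)
    if kind == "horizontal":
        # carves the anterior-inferior middle lobe; absent near the apex
        return cy + ay * (2.0 * u - 1.4)
    raise ParameterError(f"unknown fissure kind {kind!r}")


def _thorax_geometry(shape: tuple[int, int, int]) -> _Geometry:
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nx, dtype=float),
        indexing="ij",
    )
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2

    body = (
        ((zz - cz) / (0.48 * nz)) ** 2
        + ((yy - cy) / (0.44 * ny)) ** 2
        + ((xx - cx) / (0.47 * nx)) ** 2
    ) <= 1.0

    az, ay, ax = 0.34 * nz, 0.24 * ny, 0.14 * nx
    labels = np.zeros(shape, dtype=np.int16)
    lung_params: dict[str, dict] = {}
    for side, x_off in (("right", -0.21 * nx), ("left", +0.21 * nx)):
        lcx = cx + x_off
        lung = (
            ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - lcx) / ax) ** 2
        ) <= 1.0
        y_obl = _boundary_y(cy, ay, az, cz, zz, "oblique")
        if side == "left":
            labels[lung & (yy >= y_obl)] = LOBE_LABELS["LLL"]
            labels[lung & (yy < y_obl)] = LOBE_LABELS["LUL"]
        else:
            y_hor = _boundary_y(cy, ay, az, cz, zz, "horizontal")
            lower = lung & (yy >= y_obl)
            middle = lung & ~lower & (yy <= y_hor)
            upper = lung & ~lower & ~middle
            labels[lower] = LOBE_LABELS["RLL"]
            labels[middle] = LOBE_LABELS["RML"]
            labels[upper] = LOBE_LABELS["RUL"]
        lung_params[side] = {
            "center": (cz, cy, lcx),
            "semiaxes": (az, ay, ax),
        }
    return _Geometry(body=body, labels=labels, lung_params=lung_params)


def _make_traces(
    labels: np.ndarray,
    geometry: _Geometry,
    slice_step: int,
    jitter_sd_vox: float = 0.0,
    rng: np.random.Generator | None = None,
) -> FissureTraceSet:
    """Ground-truth (optionally jittered) fissure traces.

    Jitter, when requested, shifts each traced boundary line by an independent
    Gaussian offset in y per slice — a crude model of a human measurer's hand.
    """
    if jitter_sd_vox and rng is None:
        raise ParameterError("jitter requires an rng")
    traces = FissureTraceSet()
    nz = labels.shape[0]
    boundaries = [
        ("left", "oblique", "LUL", "LLL", True),
        ("right", "oblique", "RUL", "RLL", True),
        ("right", "horizontal", "RUL", "RML", False),
    ]
    side_masks = {
        "right": np.isin(labels, [LOBE_LABELS[l] for l in ("RUL", "RML", "RLL")]),
        "left": np.isin(labels, [LOBE_LABELS[l] for l in ("LUL", "LLL")]),
    }
    for side, kind, above, below, above_is_anterior in boundaries:
        cz, cy, _ = geometry.lung_params[side]["center"]
        az, ay, _ = geometry.lung_params[side]["semiaxes"]
        for z in range(0, nz, slice_step):
            on_slice = side_masks[side][z]
            if not on_slice.any():
                continue
            xs = np.where(on_slice.any(axis=0))[0]
            x_lo, x_hi = xs.min() - 1.0, xs.max() + 1.0
            y_b = float(_boundary_y(cy, ay, az, cz, np.array([z]), kind)[0])
            if jitter_sd_vox:
                y_b += float(rng.normal(0.0, jitter_sd_vox))
            # Vertex order encodes which side is lobe_above (left of travel):
            # anterior lobe_above -> traverse in -x; posterior -> +x.
            if above_is_anterior:
                vertices = np.array([[x_hi, y_b], [x_lo, y_b]])
            else:
                vertices = np.array([[x_lo, y_b], [x_hi, y_b]])
            traces.add(TracePolyline(z, above, below, vertices))
    return traces


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def _vessel_mask(geometry: _Geometry, shape: tuple[int, int, int]) -> np.ndarray:
    """One soft-tissue tube per lung, running axially through the hilum."""
    nz, ny, nx = shape
    zz = np.arange(nz, dtype=float)[:, None, None]
    yy = np.arange(ny, dtype=float)[None, :, None]
    xx = np.arange(nx, dtype=float)[None, None, :]
    mask = np.zeros(shape, dtype=bool)
    for side in ("right", "left"):
        cz, cy, lcx = geometry.lung_params[side]["center"]
        az, _, _ = geometry.lung_params[side]["semiaxes"]
        in_z = (np.abs(zz - cz) <= 0.7 * az)
        tube = ((yy - cy) ** 2 + (xx - lcx) ** 2) <= 1.2**2
        mask |= in_z & tube
    return mask


def _perfusion_density(config: PhantomConfig, labels: np.ndarray) -> np.ndarray:
    """Noise-free perfusion density, normalised to sum 1."""
    nz, ny, nx = labels.shape
    density = np.zeros(labels.shape, dtype=float)
    for lobe, lab in LOBE_LABELS.items():
        sel = labels == lab
        count = int(sel.sum())
        if count:
            density[sel] = config.lobar_flow_fractions[lobe] / count
    if config.gravity_gradient:
        t = (np.arange(ny, dtype=float) / max(ny - 1, 1))[None, :, None]
        density *= 1.0 + config.gravity_gradient * t
    if config.dropout_lesions:
        zz = np.arange(nz, dtype=float)[:, None, None]
        yy = np.arange(ny, dtype=float)[None, :, None]
        xx = np.arange(nx, dtype=float)[None, None, :]
        for (lz, ly, lx), radius, scale in config.dropout_lesions:
            sphere = ((zz - lz) ** 2 + (yy - ly) ** 2 + (xx - lx) ** 2) <= float(radius) ** 2
            density[sphere] *= float(scale)
    total = density.sum()
    if total <= 0:
        raise ParameterError("perfusion density vanished (lesions removed all flow)")
    return density / total


def generate_thorax_phantom(
    config: PhantomConfig,
) -> tuple[VoxelVolume, VoxelVolume, PhantomTruth]:
    """Build one synthetic study: (ct_volume, spect_volume, truth).

    Deterministic for a fixed ``config.seed``; the only stochastic step is the
    Poisson count sampling of the SPECT volume.
    """
    config.validate()
    shape = tuple(int(n) for n in config.grid_shape)
    geometry = _thorax_geometry(shape)
    labels = geometry.labels
    lung = labels > 0

    ct = np.full(shape, HU_AIR)
    ct[geometry.body] = HU_SOFT_TISSUE
    ct[lung] = HU_LUNG
    if config.vessels:
        ct[_vessel_mask(geometry, shape) & lung] = HU_SOFT_TISSUE

    density = _perfusion_density(config, labels)
    fractions = {
        lobe: float(density[labels == lab].sum()) for lobe, lab in LOBE_LABELS.items()
    }
    norm = sum(fractions.values())
    fractions = {k: v / norm for k, v in fractions.items()}

    sigma_vox = config.psf_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / config.voxel_size_mm
    expected = gaussian_filter(density, sigma=sigma_vox) if sigma_vox > 0 else density.copy()
    expected *= config.total_counts / expected.sum()
    rng = np.random.default_rng(config.seed)
    counts = rng.poisson(expected).astype(float)

    spacing = (config.voxel_size_mm,) * 3
    traces = _make_traces(labels, geometry, config.trace_slice_step)
    truth = PhantomTruth(
        lobe_labels=labels,
        lobar_perfusion_fractions=fractions,
        fissure_traces=traces,
        density=density,
        spacing_mm=spacing,
    )
    return (
        VoxelVolume(ct, spacing),
        VoxelVolume(counts, spacing),
        truth,
    )


def perturbed_traces(config: PhantomConfig, jitter_sd_vox: float, seed: int) -> FissureTraceSet:
    """Fissure traces for ``config``'s anatomy with per-slice Gaussian jitter.

    Emulates an independent human measurer re-tracing the interlobar lines;
    two calls with different seeds give the paired inputs of an interobserver
    study.
    """
    config.validate()
    if jitter_sd_vox < 0:
        raise ParameterError("jitter_sd_vox must be >= 0")
    geometry = _thorax_geometry(tuple(int(n) for n in config.grid_shape))
    rng = np.random.default_rng(seed)
    return _make_traces(
        geometry.labels, geometry, config.trace_slice_step, jitter_sd_vox=jitter_sd_vox, rng=rng
    )


# --------------------------------------------------------------------------
# planar projection
# --------------------------------------------------------------------------


def project_planar(spect: VoxelVolume | np.ndarray, direction: str) -> np.ndarray:
    """Project a SPECT volume to a 2-D planar view by summing along the
    anterior–posterior axis.

    The anterior view is the raw (z, x) sum; the posterior view is the same
    sum mirrored along x, as a camera behind the patient sees left and right
    swapped. Total counts are conserved exactly in both views.
    """
    values = spect.values if isinstance(spect, VoxelVolume) else np.asarray(spect)
    if values.ndim != 3:
        raise ParameterError("planar projection needs a 3-D volume")
    if (values < 0).any():
        raise ParameterError("SPECT volume must be non-negative")
    image = values.sum(axis=1)
    if direction == "anterior":
        return image
    if direction == "posterior":
        return image[:, ::-1].copy()
    raise ParameterError(f"direction must be 'anterior' or 'posterior', got {direction!r}")
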