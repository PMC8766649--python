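"""Perfusion quantification: lobar fractions, planar conjugate-view side
fractions, and the interobserver analysis."""

import numpy as np
import pytest

from ppolung import (
    DegenerateInputError,
    LOBE_LABELS,
    LOBES,
    ParameterError,
    PhantomConfig,
    interobserver_agreement,
    lobar_fractions,
    planar_side_fraction,
    project_planar,
    resected_fraction,
    side_fractions,
    side_rois_from_labels,
)
from ppolung.lungseg import split_lobes
from ppolung.perfquant import InterobserverResult
from ppolung.phantom import generate_thorax_phantom, perturbed_traces


class TestLobarFractions:
    def test_uniform_density_gives_volume_shares(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[0] = LOBE_LABELS["RLL"]  # 16 voxels
        labels[1] = LOBE_LABELS["RUL"]
        labels[2] = LOBE_LABELS["LUL"]
        labels[3] = LOBE_LABELS["LLL"]
        spect = np.ones((4, 4, 4))
        perf = lobar_fractions(spect, labels)
        assert perf.fractions["RLL"] == pytest.approx(0.25, abs=1e-12)
        assert perf.fractions["RML"] == 0.0
        assert sum(perf.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_counts_in_one_lobe(self):
        labels = np.zeros((3, 3, 3), dtype=np.int16)
        labels[0] = LOBE_LABELS["LUL"]
        labels[1] = LOBE_LABELS["LLL"]
        spect = np.zeros((3, 3, 3))
        spect[0] = 5.0
        perf = lobar_fractions(spect, labels)
        assert perf.fractions["LUL"] == 1.0
        assert perf.fractions["LLL"] == 0.0

    def test_background_counts_excluded(self):
        labels = np.zeros((3, 3, 3), dtype=np.int16)
        labels[0, 0, 0] = LOBE_LABELS["RUL"]
        spect = np.ones((3, 3, 3))  # 26 background voxels carry counts
        perf = lobar_fractions(spect, labels)
        assert perf.total == 1.0
        assert perf.fractions["RUL"] == 1.0

    def test_noiseless_phantom_close_to_truth(self, clean_phantom):
        """With the PSF applied but no Poisson step, the only error is PSF
        leakage across lobe boundaries: fractions within 0.005 of truth."""
        config, _, _, truth = clean_phantom
        from scipy.ndimage import gaussian_filter

        sigma = config.psf_fwhm_mm / 2.3548200450309493 / config.voxel_size_mm
        noiseless = gaussian_filter(truth.density, sigma) * config.total_counts
        perf = lobar_fractions(noiseless, truth.lobe_labels)
        for lobe in LOBES:
            assert perf.fractions[lobe] == pytest.approx(
                truth.lobar_perfusion_fractions[lobe], abs=0.005
            )

    def test_scale_invariance(self, default_phantom):
        _, _, spect, truth = default_phantom
        perf1 = lobar_fractions(spect.values, truth.lobe_labels)
        perf2 = lobar_fractions(2.0 * spect.values, truth.lobe_labels)
        for lobe in LOBES:
            assert perf1.fractions[lobe] == pytest.approx(perf2.fractions[lobe], abs=1e-12)

    def test_errors(self):
        with pytest.raises(Exception):
            lobar_fractions(np.ones((3, 3, 3)), np.zeros((4, 4, 4), dtype=np.int16))
        with pytest.raises(DegenerateInputError):
            lobar_fractions(np.zeros((3, 3, 3)), np.full((3, 3, 3), 1, dtype=np.int16))
        with pytest.raises(ParameterError):
            lobar_fractions(np.full((3, 3, 3), -1.0), np.full((3, 3, 3), 1, dtype=np.int16))


class TestResectedFraction:
    def _perf(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        for i, lobe in enumerate(LOBES):
            labels[:, i % 4, i % 4] = LOBE_LABELS[lobe]
        return lobar_fractions(np.ones((4, 4, 4)), labels)

    def test_additivity_and_normalisation(self, default_phantom):
        _, _, spect, truth = default_phantom
        perf = lobar_fractions(spect.values, truth.lobe_labels)
        single = resected_fraction(perf, {"RLL"})
        assert single == pytest.approx(perf.fractions["RLL"], abs=1e-15)
        combo = resected_fraction(perf, {"RUL", "RML"})
        assert combo == pytest.approx(perf.fractions["RUL"] + perf.fractions["RML"], abs=1e-12)
        assert resected_fraction(perf, set(LOBES)) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_inputs(self, default_phantom):
        _, _, spect, truth = default_phantom
        perf = lobar_fractions(spect.values, truth.lobe_labels)
        with pytest.raises(ParameterError):
            resected_fraction(perf, set())
        with pytest.raises(ParameterError):
            resected_fraction(perf, {"XXL"})


class TestPlanarSideFraction:
    def test_symmetric_phantom_gives_half(self):
        config = PhantomConfig(
            seed=2,
            gravity_gradient=0.0,
            vessels=False,
            lobar_flow_fractions={"RUL": 0.25, "RML": 0.0, "RLL": 0.25, "LUL": 0.25, "LLL": 0.25},
            total_counts=5e6,
        )
        _, spect, truth = generate_thorax_phantom(config)
        left, right = side_rois_from_labels(truth.lobe_labels)
        planar = planar_side_fraction(
            project_planar(spect, "anterior"), project_planar(spect, "posterior"), left, right
        )
        assert planar["left"] == pytest.approx(0.5, abs=0.01)
        assert planar["left"] + planar["right"] == pytest.approx(1.0, abs=1e-9)

    def test_identical_views_reduce_to_count_ratio(self):
        anterior = np.zeros((4, 6))
        anterior[:, :3] = 5.0  # left ROI sum 60
        anterior[:, 3:] = 10.0 / 3  # right ROI sum 40
        posterior = anterior[:, ::-1].copy()  # the mirrored identical view
        left_roi = np.zeros((4, 6), dtype=bool)
        left_roi[:, :3] = True
        right_roi = ~left_roi
        planar = planar_side_fraction(anterior, posterior, left_roi, right_roi)
        assert planar["left"] == pytest.approx(0.6, abs=1e-12)

    def test_matches_volumetric_fraction(self, default_phantom):
        """Attenuation-free conjugate views: planar side fraction equals the
        volumetric side fraction within 0.01 (direct summation oracle)."""
        _, _, spect, truth = default_phantom
        left, right = side_rois_from_labels(truth.lobe_labels)
        planar = planar_side_fraction(
            project_planar(spect, "anterior"), project_planar(spect, "posterior"), left, right
        )
        vol = side_fractions(lobar_fractions(spect.values, truth.lobe_labels))
        assert planar["left"] == pytest.approx(vol["left"], abs=0.01)
        assert planar["right"] == pytest.approx(vol["right"], abs=0.01)

    def test_degenerate_and_invalid(self):
        zeros = np.zeros((4, 4))
        roi = np.zeros((4, 4), dtype=bool)
        roi[:, :2] = True
        with pytest.raises(DegenerateInputError):
            planar_side_fraction(zeros, zeros, roi, ~roi)
        with pytest.raises(ParameterError):
            planar_side_fraction(zeros, zeros, roi, roi)  # overlapping ROIs


class TestSideLobeConsistency:
    def test_right_side_fraction_is_sum_of_right_lobes(self, default_phantom):
        _, _, spect, truth = default_phantom
        perf = lobar_fractions(spect.values, truth.lobe_labels)
        sides = side_fractions(perf)
        assert sides["right"] == pytest.approx(
            perf.fractions["RUL"] + perf.fractions["RML"] + perf.fractions["RLL"], abs=1e-12
        )
        assert sides["left"] + sides["right"] == pytest.approx(1.0, abs=1e-9)


class TestInterobserver:
    def test_identical_measurements(self):
        a = [0.18, 0.08, 0.25, 0.22, 0.27]
        res = interobserver_agreement(a, list(a))
        assert res.pearson_r == 1.0
        assert res.bland_altman.mean_difference == 0.0
        assert res.bland_altman.lower_loa == res.bland_altman.upper_loa == 0.0
        assert res.abs_differences.max == 0.0

    def test_constant_offset(self):
        a = np.array([10.0, 20.0, 30.0, 40.0])
        res = interobserver_agreement(a, a + 1.0)
        assert res.bland_altman.mean_difference == pytest.approx(-1.0, abs=1e-12)
        assert res.bland_altman.sd_difference == pytest.approx(0.0, abs=1e-12)
        assert abs(res.pearson_r - 1.0) < 1e-12

    def test_jittered_traces_match_direct_recomputation(self, default_phantom):
        """Two seeded 'measurers' re-trace the phantom; the agreement
        statistics must match a from-scratch numpy recomputation."""
        config, ct, spect, truth = default_phantom
        from ppolung.lungseg import binarize_ct, close_mask, extract_lung_field

        lung_field = extract_lung_field(close_mask(binarize_ct(ct), 2))
        fractions = {}
        for name, seed in (("A", 101), ("B", 202)):
            traces = perturbed_traces(config, jitter_sd_vox=0.7, seed=seed)
            labels = split_lobes(lung_field, traces)
            perf = lobar_fractions(spect.values, labels)
            fractions[name] = [perf.fractions[l] * 100 for l in LOBES]
        a = np.array(fractions["A"])
        b = np.array(fractions["B"])
        res = interobserver_agreement(a, b)
        # direct-formula oracle
        d = a - b
        assert res.bland_altman.mean_difference == pytest.approx(d.mean(), abs=1e-12)
        assert res.bland_altman.sd_difference == pytest.approx(d.std(ddof=1), abs=1e-12)
        r_direct = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert res.pearson_r == pytest.approx(r_direct, abs=1e-12)
        assert res.abs_differences.mean == pytest.approx(np.abs(d).mean(), abs=1e-12)
        # and the jitter is small enough that the measurers agree closely
        assert res.pearson_r > 0.9

    def test_too_few_pairs(self):
        from ppolung.errors import InsufficientDataError

        with pytest.raises(InsufficientDataError):
            interobserver_agreement([1.0, 2.0], [1.0, 2.0])
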