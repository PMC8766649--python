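"""Segmentation chain: binarization, closing, lung-field extraction, and
trace-based lobe splitting."""

import numpy as np
import pytest
from scipy import ndimage

from ppolung import (
    DegenerateAnatomyError,
    LOBE_LABELS,
    OpenBoundaryError,
    ParameterError,
    TraceInconsistencyError,
    binarize_ct,
    close_mask,
    extract_lung_field,
    split_lobes,
)
from ppolung.lungseg import lobe_volume_report
from ppolung.phantom import HU_LUNG, HU_SOFT_TISSUE
from ppolung.traces import FissureTraceSet

from conftest import box_traces, const_y_polyline, make_box_lungs


class TestBinarize:
    def test_uniform_volumes(self):
        assert binarize_ct(np.full((4, 4, 4), HU_LUNG), -320.0).all()
        assert not binarize_ct(np.full((4, 4, 4), HU_SOFT_TISSUE), -320.0).any()

    def test_phantom_lung_geometry_minus_vessels(self, default_phantom):
        """Inside the body, the sub-threshold voxels are exactly the lung
        parenchyma; embedded vessel voxels are the only lung voxels missed."""
        _, ct, _, truth = default_phantom
        mask = binarize_ct(ct, -320.0).astype(bool)
        lung = truth.lobe_labels > 0
        # mask = lung minus vessels, plus outside air
        outside_air = mask & ~lung
        missed = lung & ~mask  # vessel voxels
        assert 0 < missed.sum() < 0.05 * lung.sum()
        assert (mask | missed | ~lung).all()  # every lung voxel is mask or vessel
        # outside air touches the border; vessels are interior
        assert outside_air[0].any()

    def test_nonfinite_threshold(self):
        with pytest.raises(ParameterError):
            binarize_ct(np.zeros((3, 3, 3)), np.inf)


class TestClosing:
    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        mask = (rng.random((10, 10, 10)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(close_mask(mask, 0), mask)

    def test_fills_interior_hole(self):
        """Connected-component oracle on the complement: a radius-2 hole in a
        solid ellipsoid disappears after radius-3 closing."""
        zz, yy, xx = np.mgrid[0:24, 0:24, 0:24]
        mask = (((zz - 12) / 9) ** 2 + ((yy - 12) / 8) ** 2 + ((xx - 12) / 7) ** 2) <= 1
        hole = ((zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2) <= 2**2
        holed = (mask & ~hole).astype(np.uint8)
        _, n_before = ndimage.label(~holed.astype(bool))
        assert n_before == 2  # outside + hole
        closed = close_mask(holed, 3)
        _, n_after = ndimage.label(~closed.astype(bool))
        assert n_after == 1
        assert (closed.astype(bool) >= holed.astype(bool)).all()

    def test_all_zero_stays_zero(self):
        assert close_mask(np.zeros((8, 8, 8), dtype=np.uint8), 2).sum() == 0

    def test_idempotent(self):
        lung = make_box_lungs()
        once = close_mask(lung, 2)
        np.testing.assert_array_equal(close_mask(once, 2), once)

    def test_negative_radius(self):
        with pytest.raises(ParameterError):
            close_mask(np.zeros((3, 3, 3)), -1)


class TestLungField:
    def test_spurious_blob_removed(self):
        lung = make_box_lungs()
        lung[2, 2, 11:13] = 1  # 2-voxel interior blob
        lung[3, 2, 11] = 1
        extracted = extract_lung_field(lung)
        expected = make_box_lungs()
        np.testing.assert_array_equal(extracted, expected)

    def test_two_clean_components_unchanged(self):
        lung = make_box_lungs()
        np.testing.assert_array_equal(extract_lung_field(lung), lung)

    def test_border_touching_component_discarded(self):
        lung = make_box_lungs()
        lung[:, :, 0] = 1  # slab on the border
        np.testing.assert_array_equal(extract_lung_field(lung), make_box_lungs())

    def test_empty_mask_errors(self):
        with pytest.raises(DegenerateAnatomyError):
            extract_lung_field(np.zeros((8, 8, 8), dtype=np.uint8))

    def test_single_component_errors(self):
        lung = np.zeros((16, 16, 16), dtype=np.uint8)
        lung[4:12, 4:12, 4:12] = 1
        with pytest.raises(DegenerateAnatomyError):
            extract_lung_field(lung)


class TestSplitLobes:
    def test_constant_plane_split_matches_analytic_counts(self):
        """Constant-y fissures traced on every slice: the label map must split
        the boxes exactly at those planes (analytic voxel counts)."""
        lung = make_box_lungs()
        labels = split_lobes(lung, box_traces(range(4, 20)))
        # left box: y 6..17, boundary 12.5 -> LUL y 6..12 (7 rows), LLL 13..17 (5)
        n_z, n_x = 16, 6
        assert (labels == LOBE_LABELS["LUL"]).sum() == 7 * n_z * n_x
        assert (labels == LOBE_LABELS["LLL"]).sum() == 5 * n_z * n_x
        # right box: RLL y>=12.5 -> 5 rows; RML y<=9.5 -> 4 rows; RUL rest -> 3
        assert (labels == LOBE_LABELS["RLL"]).sum() == 5 * n_z * n_x
        assert (labels == LOBE_LABELS["RML"]).sum() == 4 * n_z * n_x
        assert (labels == LOBE_LABELS["RUL"]).sum() == 3 * n_z * n_x
        # partition: every lung voxel labeled, background untouched
        assert ((labels > 0) == lung.astype(bool)).all()

    def test_tie_break_on_polyline_goes_to_inferior_lobe(self):
        lung = make_box_lungs()
        labels = split_lobes(lung, box_traces(range(4, 20), y_left=10.0))
        # voxels exactly at y=10 on the left must be LLL (lobe_below)
        assert (labels[:, 10, 15:21][lung[:, 10, 15:21] > 0] == LOBE_LABELS["LLL"]).all()

    def test_interpolation_of_constant_boundary(self):
        """Tracing only the first and last slices of an axially uniform lung
        reproduces the same boundary on every intermediate slice."""
        lung = make_box_lungs()
        sparse = split_lobes(lung, box_traces([4, 19]))
        dense = split_lobes(lung, box_traces(range(4, 20)))
        np.testing.assert_array_equal(sparse, dense)

    def test_trace_order_invariance(self):
        lung = make_box_lungs()
        traces = box_traces(range(4, 20))
        shuffled = FissureTraceSet(polylines=list(reversed(traces.polylines)))
        np.testing.assert_array_equal(split_lobes(lung, traces), split_lobes(lung, shuffled))

    def test_phantom_truth_recovery(self, default_phantom):
        """Labels recovered from ground-truth traces agree with the truth
        label map on at least 99% of lung voxels."""
        _, ct, _, truth = default_phantom
        lung_field = extract_lung_field(close_mask(binarize_ct(ct), 2))
        labels = split_lobes(lung_field, truth.fissure_traces)
        lung = truth.lobe_labels > 0
        agreement = (labels[lung] == truth.lobe_labels[lung]).mean()
        assert agreement >= 0.99

    def test_open_boundary_rejected(self):
        lung = make_box_lungs()
        traces = box_traces(range(4, 20))
        # truncate one left polyline so it stops short of the lung extent
        bad = FissureTraceSet()
        for p in traces.polylines:
            if p.boundary_id == "LUL-LLL" and p.slice_index == 10:
                bad.add(const_y_polyline(10, "LUL", "LLL", 12.5, x0=16.0, x1=18.0))
            else:
                bad.add(p)
        with pytest.raises(OpenBoundaryError):
            split_lobes(lung, bad)

    def test_duplicate_trace_rejected(self):
        lung = make_box_lungs()
        traces = box_traces(range(4, 20))
        traces.add(const_y_polyline(10, "LUL", "LLL", 11.0))
        with pytest.raises(TraceInconsistencyError):
            split_lobes(lung, traces)

    def test_crossing_traces_rejected(self):
        lung = make_box_lungs()
        traces = FissureTraceSet()
        for z in range(4, 20):
            traces.add(const_y_polyline(z, "LUL", "LLL", 12.5))
            traces.add(const_y_polyline(z, "RUL", "RLL", 12.5))
            if z == 10:
                # RUL-RML polyline slanted across the oblique line
                traces.add(
                    const_y_polyline(z, "RUL", "RML", 9.5, above_anterior=False)
                )
                traces.polylines[-1].vertices[:, 1] = [6.0, 16.0]  # now crosses y=12.5
            else:
                traces.add(const_y_polyline(z, "RUL", "RML", 9.5, above_anterior=False))
        with pytest.raises(TraceInconsistencyError):
            split_lobes(lung, traces)

    def test_missing_boundary_rejected(self):
        lung = make_box_lungs()
        traces = FissureTraceSet()
        for z in range(4, 20):
            traces.add(const_y_polyline(z, "LUL", "LLL", 12.5))
            traces.add(const_y_polyline(z, "RUL", "RLL", 12.5))  # no RUL-RML
        with pytest.raises(ParameterError):
            split_lobes(lung, traces)


def test_lobe_volume_report(default_phantom):
    _, _, _, truth = default_phantom
    report = lobe_volume_report(truth.lobe_labels, (3.9, 3.9, 3.9))
    assert set(report["lobe"]) == set(LOBE_LABELS)
    total_vox = int(report["voxel_count"].sum())
    assert total_vox == int((truth.lobe_labels > 0).sum())
    assert report["volume_mL"].sum() == pytest.approx(total_vox * 3.9**3 / 1000.0)
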