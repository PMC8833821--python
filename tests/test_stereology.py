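"""Unbiased counting frames, SURS field selection and Q_A pooling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunomargin.stereology import (
    FRAME_AREA_LADDER,
    MARGIN_FRAME_AREA,
    CountingFrame,
    SamplingDesign,
    adaptive_frame_area,
    adaptive_frames_per_fov,
    count_in_frame,
    default_design,
    estimate_qa,
    estimate_roi_qa,
    layout_frames,
    sample_fovs,
)
from immunomargin.synthesize import sample_points_in_mask


def brute_force_count(xs, ys, frame):
    """Independent forbidden-line oracle: explicit per-point comparisons."""
    n = 0
    for x, y in zip(xs, ys):
        if frame.x0 < x <= frame.x0 + frame.width and frame.y0 < y <= frame.y0 + frame.height:
            n += 1
    return n


class TestCountingRule:
    def test_empty_point_set(self):
        frame = CountingFrame(0.0, 0.0, 10.0, 10.0)
        assert count_in_frame(pd.DataFrame(columns=["x_um", "y_um"]), frame) == 0

    def test_forbidden_and_acceptance_edges(self):
        frame = CountingFrame(0.0, 0.0, 10.0, 10.0)

        def one(x, y):
            return count_in_frame(pd.DataFrame({"x_um": [x], "y_um": [y]}), frame)

        assert one(0.0, 5.0) == 0  # left edge: forbidden line
        assert one(5.0, 0.0) == 0  # bottom edge: forbidden line
        assert one(10.0, 10.0) == 1  # top-right corner: acceptance lines
        assert one(10.0, 5.0) == 1  # right edge included
        assert one(5.0, 5.0) == 1  # interior

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xs = rng.uniform(-5, 25, size=200)
        ys = rng.uniform(-5, 25, size=200)
        frame = CountingFrame(
            rng.uniform(0, 10), rng.uniform(0, 10), rng.uniform(1, 12), rng.uniform(1, 12)
        )
        pts = pd.DataFrame({"x_um": xs, "y_um": ys})
        assert count_in_frame(pts, frame) == brute_force_count(xs, ys, frame)

    def test_roi_mask_restricts_counts(self):
        frame = CountingFrame(0.0, 0.0, 40.0, 40.0)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:2, :] = True  # ROI = rows 0-1 -> y in [0, 20) at 10 um pixels
        pts = pd.DataFrame({"x_um": [5.0, 5.0], "y_um": [15.0, 35.0]})
        assert count_in_frame(pts, frame, roi_mask=mask, pixel_size_um=10.0) == 1


class TestEstimateQa:
    def test_worked_margin_design_example(self):
        # 100 profiles over the 48-frame margin probe (417,611 um^2 total).
        res = estimate_qa([100], [417_611.0])
        assert round(res.qa_per_mm2, 2) == 239.46

    def test_worked_pt_design_example(self):
        res = estimate_qa([50], [417_215.0])
        assert round(res.qa_per_mm2, 2) == 119.84

    def test_zero_profiles_give_zero_density(self):
        assert estimate_qa([0, 0], [100.0, 200.0]).qa_per_mm2 == 0.0

    def test_invariant_to_frame_order_and_splitting(self, rng):
        counts = rng.integers(0, 9, size=12)
        areas = rng.uniform(5000, 9000, size=12)
        full = estimate_qa(counts, areas).qa_per_mm2
        perm = rng.permutation(12)
        assert estimate_qa(counts[perm], areas[perm]).qa_per_mm2 == pytest.approx(full)
        a = estimate_qa(counts[:5], areas[:5])
        b = estimate_qa(counts[5:], areas[5:])
        pooled = (
            (a.counted_profiles + b.counted_profiles)
            / (a.total_frame_area_um2 + b.total_frame_area_um2)
            * 1e6
        )
        assert pooled == pytest.approx(full)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_qa([], [])
        with pytest.raises(ValueError):
            estimate_qa([1], [0.0])


class TestAdaptiveFrameArea:
    def test_caps_and_target_rule(self):
        assert adaptive_frame_area(1e6) == min(FRAME_AREA_LADDER)  # dense -> smallest
        assert adaptive_frame_area(0.0) == max(FRAME_AREA_LADDER)  # empty -> largest
        # density 100/mm^2, target 2 -> needs >= 20,000 um^2 -> 26,100.
        assert adaptive_frame_area(100.0) == 26100.0

    def test_frames_per_fov_tracks_ladder(self):
        assert adaptive_frames_per_fov(8700.0) == 9
        assert adaptive_frames_per_fov(34801.0) == 6

    def test_default_margin_design_matches_protocol_total(self):
        d = default_design("innM")
        assert d.n_fov * d.frames_per_fov * d.frame_area_um2 == pytest.approx(417_611.0)
        d = default_design("PT")
        assert d.n_fov * d.frames_per_fov * d.frame_area_um2 == pytest.approx(417_215.0)


class TestSampleFovs:
    def _strip_mask(self, n_cells, fov_um=100.0, pixel=10.0):
        # A 1-FOV-tall strip with exactly n_cells FOV-sized candidates.
        cells_px = int(fov_um / pixel)
        return np.ones((cells_px, n_cells * cells_px), dtype=bool)

    def test_surs_selects_arithmetic_sequence(self, rng):
        design = SamplingDesign(n_fov=8, frames_per_fov=1, frame_area_um2=400.0,
                                fov_width_um=100.0, fov_height_um=100.0)
        mask = self._strip_mask(80)
        fovs, warnings = sample_fovs(mask, 10.0, design, rng)
        assert not warnings
        xs = [f.x0 for f in fovs]
        steps = np.diff(xs)
        assert len(fovs) == 8
        assert np.allclose(steps, 10 * 100.0)  # every 10th candidate

    def test_same_seed_reproduces_placements(self):
        design = SamplingDesign(n_fov=8, frames_per_fov=1, frame_area_um2=400.0,
                                fov_width_um=100.0, fov_height_um=100.0)
        mask = self._strip_mask(37)
        a, _ = sample_fovs(mask, 10.0, design, np.random.default_rng(5))
        b, _ = sample_fovs(mask, 10.0, design, np.random.default_rng(5))
        assert a == b

    def test_small_roi_gets_single_centered_fov(self, rng):
        design = SamplingDesign(n_fov=8, frames_per_fov=1, frame_area_um2=400.0,
                                fov_width_um=500.0, fov_height_um=500.0)
        mask = np.zeros((100, 100), dtype=bool)
        mask[40:44, 40:44] = True  # 40 um blob << 500 um FOV
        fovs, warnings = sample_fovs(mask, 10.0, design, rng)
        assert len(fovs) == 1
        assert any("single centered FOV" in w for w in warnings)
        center_x = fovs[0].x0 + fovs[0].width / 2
        assert center_x == pytest.approx(420.0)

    def test_too_few_candidates_reduces_with_warning(self, rng):
        design = SamplingDesign(n_fov=8, frames_per_fov=1, frame_area_um2=400.0,
                                fov_width_um=100.0, fov_height_um=100.0)
        mask = self._strip_mask(3)
        fovs, warnings = sample_fovs(mask, 10.0, design, rng)
        assert len(fovs) == 3
        assert any("only 3" in w for w in warnings)


class TestFrameLayout:
    def test_frames_fill_top_left_first_and_stay_inside_roi(self):
        design = SamplingDesign(n_fov=1, frames_per_fov=4, frame_area_um2=100.0,
                                fov_width_um=100.0, fov_height_um=100.0)
        mask = np.ones((20, 20), dtype=bool)
        mask[:, 10:] = False  # right half of a 200 um square is off-ROI
        from immunomargin.stereology import FieldOfView

        fov = FieldOfView(0.0, 0.0, 100.0, 100.0)
        frames = layout_frames(fov, design, mask, 10.0)
        assert len(frames) == 4
        assert frames[0].x0 == 0.0 and frames[0].y0 == 0.0
        for fr in frames:
            assert fr.x0 + fr.width <= 100.0  # inside the ROI half


class TestEstimatorProperties:
    def test_variance_decreases_with_more_fovs(self, disc_section):
        mask = disc_section.partition.mask("innM")
        rng = np.random.default_rng(11)
        out = {}
        for n_fov in (2, 8):
            design = SamplingDesign(n_fov=n_fov)
            qas = []
            attempts = 0
            while len(qas) < 120 and attempts < 300:
                attempts += 1
                x, y = sample_points_in_mask(mask, 10.0, 200.0, rng)
                pts = pd.DataFrame({"x_um": x, "y_um": y})
                try:
                    qas.append(estimate_roi_qa(pts, mask, 10.0, design, rng).qa_per_mm2)
                except ValueError:
                    # with 2 FOVs both may graze the band and hold no frame
                    continue
            out[n_fov] = np.var(qas)
        assert out[8] < out[2]

    def test_no_frame_fits_raises(self, rng):
        mask = np.zeros((30, 30), dtype=bool)
        mask[14:16, 14:16] = True  # 20 um speck, far smaller than any frame
        design = SamplingDesign()
        pts = pd.DataFrame({"x_um": [150.0], "y_um": [150.0]})
        with pytest.raises(ValueError, match="no counting frame"):
            estimate_roi_qa(pts, mask, 10.0, design, rng)
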