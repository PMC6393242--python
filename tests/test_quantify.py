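"""Image quantification: segmentation, ROI FIR, radial profiles, ring stats."""

import numpy as np
import pytest

from trnaflux import (
    CellImageStack,
    CytoplasmProfile,
    generate_timelapse,
    make_field,
    mean_cytoplasmic_intensity,
    radial_profile,
    ring_stats,
    roi_fir,
    segment,
)

from conftest import STARVATION, nucleus_center_px


@pytest.fixture
def noiseless_stack(small_geom, ring_profile, starvation_geom):
    times = np.arange(0.0, 91.0, 15.0)
    return generate_timelapse(small_geom, ring_profile, STARVATION,
                              starvation_geom, times)


class TestSegment:
    def test_supplied_masks_pass_through(self, noiseless_stack):
        stack, _ = noiseless_stack
        nuc, cell = segment(stack)
        np.testing.assert_array_equal(nuc, stack.nucleus_mask)
        np.testing.assert_array_equal(cell, stack.cell_mask)

    def test_constant_image_rejected(self, small_geom):
        stack = CellImageStack(
            frames=np.zeros((1, *small_geom.shape)), times=np.array([0.0]),
            pixel_size=small_geom.pixel_size,
        )
        with pytest.raises(ValueError):
            segment(stack)

    def test_otsu_segmentation_overlaps_truth(self, noiseless_stack):
        stack, _ = noiseless_stack
        bare = CellImageStack(
            frames=stack.frames, times=stack.times, pixel_size=stack.pixel_size,
            geometry=stack.geometry,  # nucleus from geometry, cell from Otsu
        )
        nuc, cell = segment(bare)
        inter = (cell & stack.cell_mask).sum()
        union = (cell | stack.cell_mask).sum()
        assert inter / union > 0.95


class TestRoiFir:
    def test_flat_two_to_one_contrast(self, small_geom):
        gt = make_field(small_geom, CytoplasmProfile("flat"), C_N=2.0, C_C=1.0)
        stack = CellImageStack(
            frames=gt.field[None], times=np.array([0.0]),
            pixel_size=small_geom.pixel_size, nucleus_mask=small_geom.masks()[0],
            cell_mask=small_geom.masks()[1], geometry=small_geom,
        )
        series = roi_fir(stack)
        assert series.fir[0] == pytest.approx(2.0, abs=1e-6)

    def test_extracted_tracks_truth_within_2pct(self, noiseless_stack):
        stack, fir_true = noiseless_stack
        series = roi_fir(stack)
        nz = fir_true.fir > 0
        rel = np.abs(series.fir[nz] - fir_true.fir[nz]) / fir_true.fir[nz]
        assert rel.max() < 0.02

    def test_starvation_end_state_reaches_three(self, noiseless_stack):
        stack, _ = noiseless_stack
        series = roi_fir(stack)
        assert series.fir[-1] == pytest.approx(3.0, rel=0.02)

    def test_noisy_extraction_unbiased(self, small_geom, ring_profile,
                                       starvation_geom):
        from trnaflux import render_frame

        times = np.array([0.0, 90.0])
        stack, fir_true = generate_timelapse(
            small_geom, ring_profile, STARVATION, starvation_geom, times,
        )
        truth = stack.frames[-1]
        gt_frame = stack.truth[-1]
        firs = []
        for seed in range(1, 101):
            noisy = render_frame(gt_frame, photons_per_unit=200.0,
                                 pixel_size=small_geom.pixel_size, seed=seed)
            one = CellImageStack(
                frames=noisy[None], times=np.array([90.0]),
                pixel_size=small_geom.pixel_size,
                nucleus_mask=stack.nucleus_mask, cell_mask=stack.cell_mask,
                geometry=small_geom,
            )
            firs.append(roi_fir(one).fir[0])
        clean = CellImageStack(
            frames=truth[None], times=np.array([90.0]),
            pixel_size=small_geom.pixel_size,
            nucleus_mask=stack.nucleus_mask, cell_mask=stack.cell_mask,
            geometry=small_geom,
        )
        assert np.mean(firs) == pytest.approx(roi_fir(clean).fir[0], rel=0.01)


class TestMeanCytoplasmAndW:
    def test_flat_cytoplasm_has_unit_w(self, small_geom):
        gt = make_field(small_geom, CytoplasmProfile("flat"), C_N=1.0, C_C=1.0)
        stack = CellImageStack(
            frames=gt.field[None], times=np.array([0.0]),
            pixel_size=small_geom.pixel_size, nucleus_mask=small_geom.masks()[0],
            cell_mask=small_geom.masks()[1], geometry=small_geom,
        )
        df = mean_cytoplasmic_intensity(stack)
        assert df.w.iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_w_matches_generator_ground_truth(self, small_geom, decay_profile):
        gt = make_field(small_geom, decay_profile, C_N=0.5, C_C=1.0)
        stack = CellImageStack(
            frames=gt.field[None], times=np.array([0.0]),
            pixel_size=small_geom.pixel_size, nucleus_mask=small_geom.masks()[0],
            cell_mask=small_geom.masks()[1], geometry=small_geom,
        )
        df = mean_cytoplasmic_intensity(stack)
        assert df.w.iloc[0] == pytest.approx(gt.w_true, rel=0.01)
        assert df.w.iloc[0] < 1.0

    def test_inverted_profile_warns(self, small_geom):
        # brighter at the periphery than perinuclearly: w > 1
        nuc, cell = small_geom.masks()
        r = small_geom.radius_map()
        frame = np.where(cell & ~nuc, np.exp(r - 7.0), 0.0)
        frame[nuc] = 1.0
        stack = CellImageStack(
            frames=frame[None], times=np.array([0.0]),
            pixel_size=small_geom.pixel_size, nucleus_mask=nuc, cell_mask=cell,
            geometry=small_geom,
        )
        with pytest.warns(UserWarning, match="profile inversion"):
            mean_cytoplasmic_intensity(stack)


class TestRadialProfile:
    def test_recovers_generating_profile(self, small_geom, ring_profile):
        gt = make_field(small_geom, ring_profile, C_N=0.4, C_C=1.0)
        center = nucleus_center_px(small_geom)
        prof = radial_profile(gt.field, center, small_geom.pixel_size)
        # compare outside the boundary-blur zones, inside the cell
        sel = (prof.r > 8.0) & (prof.r < 8.8)
        expected = ring_profile.shape(prof.r[sel], small_geom.nucleus_radius)
        expected = expected / ring_profile.shape(
            np.array([8.5]), small_geom.nucleus_radius
        )[0] * gt.field[small_geom.masks()[1] & ~small_geom.masks()[0]].max()
        got = prof.intensity[sel] * prof.normalization_constant
        rms = np.sqrt(np.mean((got / got.max() - expected / expected.max()) ** 2))
        assert rms < 0.01

    def test_first_frame_self_normalizes_to_one(self, small_geom, ring_profile):
        gt = make_field(small_geom, ring_profile, C_N=0.4, C_C=1.0)
        prof = radial_profile(gt.field, nucleus_center_px(small_geom),
                              small_geom.pixel_size)
        assert prof.intensity.max() == pytest.approx(1.0)

    def test_shared_normalization_across_frames(self, small_geom, ring_profile):
        early = make_field(small_geom, ring_profile, C_N=0.2, C_C=1.0)
        late = make_field(small_geom, ring_profile, C_N=3.0, C_C=1.0)
        center = nucleus_center_px(small_geom)
        p0 = radial_profile(early.field, center, small_geom.pixel_size)
        p1 = radial_profile(late.field, center, small_geom.pixel_size,
                            normalization_constant=p0.normalization_constant)
        # nuclear plateau of the late frame on the early frame's scale
        nuc_sel = p1.r < 5.0
        assert p1.intensity[nuc_sel].mean() == pytest.approx(
            3.0 / p0.normalization_constant, rel=0.01
        )

    def test_nucleus_interior_is_flat(self, small_geom, ring_profile):
        gt = make_field(small_geom, ring_profile, C_N=2.0, C_C=1.0)
        prof = radial_profile(gt.field, nucleus_center_px(small_geom),
                              small_geom.pixel_size)
        interior = prof.intensity[prof.r < 6.0]  # clear of boundary blur
        assert interior.std() / interior.mean() < 0.01

    def test_rotation_equivariance(self, small_geom, ring_profile):
        gt = make_field(small_geom, ring_profile, C_N=0.5, C_C=1.0)
        center = nucleus_center_px(small_geom)
        p = radial_profile(gt.field, center, small_geom.pixel_size)
        rot = np.rot90(gt.field)
        c_rot = (gt.field.shape[1] - 1 - center[1], center[0])
        p_rot = radial_profile(rot, c_rot, small_geom.pixel_size)
        np.testing.assert_allclose(p.intensity, p_rot.intensity, atol=0.01)

    def test_center_outside_image_rejected(self, small_geom, ring_profile):
        gt = make_field(small_geom, ring_profile, C_N=0.5)
        with pytest.raises(ValueError):
            radial_profile(gt.field, (-5.0, 10.0), small_geom.pixel_size)


class TestRingStats:
    def _profile(self, geom, profile, C_N=0.4):
        gt = make_field(geom, profile, C_N=C_N, C_C=1.0)
        return radial_profile(gt.field, nucleus_center_px(geom), geom.pixel_size)

    def test_peaked_ring_detected_at_expected_radius(self, small_geom, ring_profile):
        stats = ring_stats(self._profile(small_geom, ring_profile), 7.0)
        assert stats.present
        assert stats.peak_radius == pytest.approx(8.0, abs=0.3)

    def test_monotone_decay_has_no_ring(self, small_geom, decay_profile):
        assert not ring_stats(self._profile(small_geom, decay_profile), 7.0).present

    def test_flat_cytoplasm_has_no_ring(self, small_geom):
        prof = self._profile(small_geom, CytoplasmProfile("flat"))
        assert not ring_stats(prof, 7.0).present
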