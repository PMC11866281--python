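"""Joint-tissue segmentation: boundary, hole and merge policies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import shg4d as s
from shg4d.phantom import envelope_mask
from shg4d.segmentation import EmptyMaskError, SegmentationParams

from conftest import tiny_spec


class TestThresholding:
    def test_noiseless_slab_mask_matches_envelope(self, aligned_slab_spec, aligned_slab_stack):
        mask = s.segment_tissue(aligned_slab_stack)
        env = envelope_mask(aligned_slab_spec, 0.0)
        assert abs(mask.voxel_count - env.sum()) / env.sum() < 0.02
        np.testing.assert_array_equal(mask.mask, env)  # crisp phantom: exact

    def test_intensity_scale_invariance(self, aligned_slab_stack):
        ref = s.segment_tissue(aligned_slab_stack).mask
        for c in (0.5, 2.0, 3.7):
            scaled = s.VoxelStack(
                forward=aligned_slab_stack.forward * c,
                epi=aligned_slab_stack.epi * c,
                spacing=aligned_slab_stack.spacing,
                timestamp_min=aligned_slab_stack.timestamp_min,
            )
            np.testing.assert_array_equal(s.segment_tissue(scaled).mask, ref)

    def test_constant_channel_rejected(self):
        stack = s.VoxelStack(
            forward=np.full((8, 8, 8), 5.0), epi=np.full((8, 8, 8), 5.0),
            spacing=(1, 1, 1), timestamp_min=0.0,
        )
        with pytest.raises(ValueError, match="constant"):
            s.segment_tissue(stack)

    def test_pure_noise_stack_flagged_as_signal_lost(self):
        rng = np.random.default_rng(0)
        noise = np.clip(rng.normal(0, 2, size=(24, 40, 48)), 0, None)
        stack = s.VoxelStack(forward=noise, epi=noise, spacing=(1, 2, 1.5), timestamp_min=0.0)
        with pytest.raises(EmptyMaskError, match="left the imaging volume or signal lost"):
            s.segment_tissue(stack)


class TestHolePolicy:
    def test_enclosed_voids_counted_as_sample_volume(self):
        spec = tiny_spec(
            nx=64, ny=48, nz=32, h0=20.0, w0=40.0, length=70.0,
            mode="dilution", swell_amplitude=0.4, tau_s_min=5.0,
            timestamps=(0.0, 30.0), void_rate_per_min=1.0, void_radius_um=(3.0, 5.0),
            stripe_contrast=0.0,
        )
        series = s.generate_stack_series(spec)
        mask = s.segment_tissue(series[1])
        env = envelope_mask(spec, 30.0)
        assert mask.provenance["cavity_voxels_filled"] > 0
        # mask volume tracks the envelope (voids filled), not the emitting volume
        emitting = (series[1].forward > 0) & env
        assert mask.voxel_count == pytest.approx(env.sum(), rel=0.02)
        assert mask.voxel_count > emitting.sum()

    def test_destruction_dimming_keeps_volume_until_snr_below_two(self):
        # constant envelope, per-voxel decay; mean SNR per stack computed
        # from the noise model: SNR = E / sqrt(E/gain + sd²)
        spec = tiny_spec(
            nx=64, ny=48, nz=32, h0=20.0, w0=40.0, length=70.0,
            mode="destruction", tau_d_min=12.0, gain=1.0, read_noise_sd=2.0,
            timestamps=(0.0, 8.0, 16.0, 24.0), stripe_contrast=0.0,
        )
        series = s.generate_stack_series(spec)
        env_n = envelope_mask(spec, 0.0).sum()
        for stack, t in zip(series, spec.timestamps):
            e = spec.base_intensity * np.exp(-t / spec.tau_d_min)
            snr = e / np.sqrt(e / spec.gain + spec.read_noise_sd**2)
            if snr < 2:
                continue
            mask = s.segment_tissue(stack)
            assert mask.voxel_count == pytest.approx(env_n, rel=0.10), f"t={t}, snr={snr:.1f}"


class TestMergePolicy:
    @staticmethod
    def _two_fragment_stack(gap_um: float) -> s.VoxelStack:
        vol = np.zeros((24, 40, 60))
        vol[6:18, 5:35, 5:25] = 100.0  # main slab
        start = 25 + int(gap_um)  # 1 μm spacing along x
        vol[6:18, 5:35, start:start + 12] = 100.0  # drifting fragment
        return s.VoxelStack(forward=vol, epi=vol, spacing=(1, 1, 1), timestamp_min=0.0)

    def test_fragment_within_merge_distance_is_merged(self):
        params = SegmentationParams(merge_distance_um=5.0, closing_radius_vox=0)
        mask = s.segment_tissue(self._two_fragment_stack(gap_um=3.0), params)
        assert mask.provenance["components_merged"] == 1
        assert mask.voxel_count == 12 * 30 * 20 + 12 * 30 * 12

    def test_fragment_beyond_merge_distance_is_dropped(self):
        params = SegmentationParams(merge_distance_um=5.0, closing_radius_vox=0)
        mask = s.segment_tissue(self._two_fragment_stack(gap_um=8.0), params)
        assert mask.provenance["components_merged"] == 0
        assert mask.voxel_count == 12 * 30 * 20

    def test_provenance_records_all_policy_parameters(self, aligned_slab_stack):
        prov = s.segment_tissue(aligned_slab_stack).provenance
        for key in (
            "threshold", "otsu", "background_floor", "smoothing_sigma_vox",
            "merge_distance_um", "closing_radius_vox", "components_found",
            "components_merged", "cavity_voxels_filled",
        ):
            assert key in prov


class TestMaskOverlap:
    def test_identical_masks_give_one(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        assert s.mask_overlap(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert s.mask_overlap(a, b) == 0.0

    def test_half_shifted_slab_matches_brute_force_count(self):
        a = np.zeros((6, 6, 20), bool)
        b = np.zeros((6, 6, 20), bool)
        a[:, :, 0:10] = True
        b[:, :, 5:15] = True
        inter = sum(
            1 for z in range(6) for y in range(6) for x in range(20) if a[z, y, x] and b[z, y, x]
        )
        union = sum(
            1 for z in range(6) for y in range(6) for x in range(20) if a[z, y, x] or b[z, y, x]
        )
        assert s.mask_overlap(a, b) == pytest.approx(inter / union)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            s.mask_overlap(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 3), bool))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        a=arrays(bool, (4, 5, 6), elements=st.booleans()),
        b=arrays(bool, (4, 5, 6), elements=st.booleans()),
    )
    def test_overlap_is_a_bounded_symmetric_similarity(self, a, b):
        j = s.mask_overlap(a, b)
        assert 0.0 <= j <= 1.0
        assert j == s.mask_overlap(b, a)
        if np.array_equal(a, b):
            assert j == 1.0
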