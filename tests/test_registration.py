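"""Rigid transforms, resampling, joint histograms, MI, and registration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxelreg.registration import (
    JointHistogram,
    RegistrationConfig,
    RegistrationError,
    RigidTransform,
    joint_histogram,
    mutual_information,
    register,
    resample_trilinear,
    roi_centroid,
    rough_align,
    zone_roi,
)
from voxelreg.volume_io import BinaryMask, Volume

from conftest import make_ramp_volume


def mi_direct_summation(counts) -> float:
    """Independent oracle: term-by-term MI summation in bits."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    out = 0.0
    pa = counts.sum(axis=1) / total
    pb = counts.sum(axis=0) / total
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            p = counts[i, j] / total
            if p > 0:
                out += p * np.log2(p / (pa[i] * pb[j]))
    return out


transforms = st.builds(
    RigidTransform.from_euler,
    st.tuples(*[st.floats(-30, 30) for _ in range(3)]),
    st.tuples(*[st.floats(-20, 20) for _ in range(3)]),
    st.tuples(*[st.floats(-10, 10) for _ in range(3)]),
)


class TestRigidTransform:
    def test_rejects_reflection(self):
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]))

    @settings(deadline=None, max_examples=50)
    @given(transforms)
    def test_inverse_composes_to_identity(self, t):
        ident = t.compose(t.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(ident.offset, 0.0, atol=1e-8)

    @settings(deadline=None, max_examples=50)
    @given(transforms, transforms)
    def test_compose_matches_sequential_application(self, a, b):
        pts = np.random.default_rng(0).uniform(-30, 30, (20, 3))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-8)

    @settings(deadline=None, max_examples=30)
    @given(transforms)
    def test_recentring_preserves_the_map(self, t):
        pts = np.random.default_rng(1).uniform(-30, 30, (10, 3))
        moved = t.with_center((5.0, -7.0, 2.0))
        assert np.allclose(t.apply(pts), moved.apply(pts), atol=1e-9)

    def test_save_load_round_trip(self, tmp_path):
        t = RigidTransform.from_euler((10, -5, 3), (1.5, 0, -2.25), (4, 4, 4))
        t.save(tmp_path / "t.txt")
        back = RigidTransform.load(tmp_path / "t.txt")
        assert np.allclose(back.rotation, t.rotation, atol=1e-12)
        assert np.allclose(back.translation, t.translation, atol=1e-12)


class TestResampleTrilinear:
    def test_identity_transform_is_exact(self, rng):
        vol = Volume(rng.normal(size=(8, 9, 10)), spacing=(1, 1, 1))
        out, valid = resample_trilinear(vol, RigidTransform.identity(), vol)
        assert np.allclose(out.data, vol.data, atol=1e-12)
        assert valid.data.all()

    def test_integer_voxel_shift_is_exact_on_overlap(self, rng):
        vol = Volume(rng.normal(size=(8, 8, 8)), spacing=(0.5, 0.5, 0.5))
        shift = RigidTransform.from_euler((0, 0, 0), (1.0, 0, 0))  # 2 voxels in x
        out, valid = resample_trilinear(vol, shift, vol)
        assert np.allclose(out.data[2:, :, :], vol.data[:-2, :, :], atol=1e-12)
        assert not valid.data[:2].any() and valid.data[2:].all()

    def test_half_voxel_shift_matches_affine_closed_form(self):
        # trilinear interpolation is exact on an affine intensity field
        vol = make_ramp_volume(spacing=(0.5, 0.5, 0.5), coeffs=(3.0, 5.0, 7.0), const=10.0)
        t = RigidTransform.from_euler((0, 0, 0), (0.25, 0.25, 0.25))
        out, valid = resample_trilinear(vol, t, vol)
        idx = np.stack(np.meshgrid(*(np.arange(n) for n in vol.shape), indexing="ij"), axis=-1)
        world = idx * 0.5
        expected = (world - 0.25) @ np.array([3.0, 5.0, 7.0]) + 10.0
        assert np.abs(out.data[valid.data] - expected[valid.data]).max() <= 1e-6


class TestRoughAlign:
    def test_identity_for_identical_landmarks(self, rng):
        pts = rng.uniform(-20, 20, (5, 3))
        t, rms = rough_align(pts, pts)
        assert rms == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)

    def test_recovers_known_rigid_motion_exactly(self, rng):
        pts = rng.uniform(-20, 20, (6, 3))
        true = RigidTransform.from_euler((10, 0, 0), (5.0, 0.0, 0.0))
        t, rms = rough_align(true.apply(pts), pts)
        assert rms <= 1e-9
        assert np.allclose(t.apply(pts), true.apply(pts), atol=1e-9)

    def test_reported_rms_matches_direct_residual(self, rng):
        fixed = rng.uniform(-20, 20, (10, 3))
        moving = fixed + rng.normal(0, 0.5, fixed.shape)
        t, rms = rough_align(fixed, moving)
        direct = np.sqrt(np.mean(np.sum((t.apply(moving) - fixed) ** 2, axis=1)))
        assert rms == pytest.approx(direct, abs=1e-12)

    def test_collinear_landmarks_rejected(self):
        line = np.outer(np.arange(4, dtype=float), [1.0, 2.0, 3.0])
        with pytest.raises(RegistrationError, match="collinear"):
            rough_align(line, line + 0.1)


class TestJointHistogram:
    def test_identical_volumes_put_all_mass_on_diagonal(self, rng):
        data = rng.uniform(0, 1000, (6, 6, 6))
        vol = Volume(data, spacing=(1, 1, 1))
        roi = BinaryMask.like(vol, np.ones(vol.shape, bool))
        cfg = RegistrationConfig(bins=8, clamp_hu=(0, 1000))
        h = joint_histogram(vol, vol, RigidTransform.identity(), roi, cfg)
        assert h.total == 216
        assert h.counts.sum() == np.trace(h.counts)

    def test_total_equals_roi_size_under_full_overlap(self, rng):
        vol = Volume(rng.uniform(0, 100, (5, 5, 5)), spacing=(1, 1, 1))
        roi_data = np.zeros(vol.shape, bool)
        roi_data[1:4, 1:4, 1:4] = True
        roi = BinaryMask.like(vol, roi_data)
        h = joint_histogram(vol, vol, RigidTransform.identity(), roi)
        assert h.total == 27

    def test_three_voxel_hand_binning(self):
        fixed = Volume(np.array([0.0, 1000.0, 1000.0]).reshape(3, 1, 1), spacing=(1, 1, 1))
        roi = BinaryMask.like(fixed, np.ones((3, 1, 1), bool))
        cfg = RegistrationConfig(bins=2, clamp_hu=(0, 1000))
        h = joint_histogram(fixed, fixed, RigidTransform.identity(), roi, cfg)
        assert np.array_equal(h.counts, [[1, 0], [0, 2]])

    def test_empty_overlap_raises(self):
        vol = Volume(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
        roi = BinaryMask.like(vol, np.ones((4, 4, 4), bool))
        far = RigidTransform.from_euler((0, 0, 0), (1000.0, 0, 0))
        with pytest.raises(RegistrationError, match="overlap"):
            joint_histogram(vol, vol, far, roi)


class TestMutualInformation:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[2, 0], [0, 2]], 1.0),
            ([[1, 1], [1, 1]], 0.0),
            ([[3, 1], [1, 3]], 0.18872187554086717),  # frozen from direct summation
        ],
    )
    def test_known_histograms(self, counts, expected):
        h = JointHistogram(np.array(counts), np.array([0, 1, 2.0]), np.array([0, 1, 2.0]))
        assert mutual_information(h) == pytest.approx(expected, abs=1e-12)
        assert mi_direct_summation(counts) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(0, 50), min_size=16, max_size=16))
    def test_nonnegative_symmetric_and_matches_oracle(self, flat):
        counts = np.array(flat).reshape(4, 4)
        if counts.sum() == 0:
            counts[0, 0] = 1
        edges = np.arange(5, dtype=float)
        h = JointHistogram(counts, edges, edges)
        mi = mutual_information(h)
        mi_t = mutual_information(JointHistogram(counts.T, edges, edges))
        assert mi >= -1e-15
        assert mi == pytest.approx(mi_t, abs=1e-12)
        assert mi == pytest.approx(mi_direct_summation(counts), abs=1e-12)


class TestZoneRoi:
    def _masks(self, shape=(12, 12, 12)):
        cb = np.zeros(shape, bool)
        cb[4:8, 4:8, 4:6] = True
        return {"CB": BinaryMask(cb, (1, 1, 1)), "ZL": BinaryMask(np.zeros(shape, bool), (1, 1, 1))}

    def test_dilation_matches_direct_morphology(self):
        from scipy import ndimage

        masks = self._masks()
        roi = zone_roi(masks, "anterior-cranial-base", margin_voxels=2)
        expected = ndimage.binary_dilation(
            masks["CB"].data, structure=np.ones((3, 3, 3), bool), iterations=2
        )
        assert np.array_equal(roi.data, expected)

    def test_zero_margin_returns_stored_mask(self):
        masks = self._masks()
        roi = zone_roi(masks, "anterior-cranial-base", margin_voxels=0)
        assert np.array_equal(roi.data, masks["CB"].data)

    def test_empty_mask_rejected(self):
        with pytest.raises(RegistrationError, match="empty"):
            zone_roi(self._masks(), "left-zygomatic-arch")

    def test_unknown_zone_rejected(self):
        with pytest.raises(RegistrationError, match="unknown"):
            zone_roi(self._masks(), "occiput")


class TestRegister:
    def test_self_registration_returns_identity(self, coarse_pair):
        fixed, _moving, truth = coarse_pair
        roi = zone_roi(truth.structure_masks, "anterior-cranial-base")
        est, diag = register(fixed, fixed, roi, RigidTransform.identity())
        assert np.linalg.norm(est.offset) <= 0.01
        assert est.rotation_angle_deg() <= 0.01
        assert diag.final_mi >= diag.initial_mi - 1e-12

    def test_final_mi_never_below_initialization(self, coarse_pair):
        fixed, moving, truth = coarse_pair
        roi = zone_roi(truth.structure_masks, "anterior-cranial-base")
        init = truth.true_transform
        est, diag = register(fixed, moving, roi, init, RegistrationConfig(max_iterations=3))
        assert diag.final_mi >= diag.initial_mi - 1e-12

    def test_mi_trace_is_recorded_per_level(self, coarse_pair):
        fixed, moving, truth = coarse_pair
        roi = zone_roi(truth.structure_masks, "anterior-cranial-base")
        _est, diag = register(fixed, moving, roi, truth.true_transform)
        assert len(diag.mi_trace) == len(diag.sample_counts) >= 1
        assert all(n > 0 for n in diag.sample_counts)

    def test_deterministic_given_config_seed(self, coarse_pair):
        fixed, moving, truth = coarse_pair
        roi = zone_roi(truth.structure_masks, "left-zygomatic-arch")
        cfg = RegistrationConfig(seed=9)
        init = truth.true_transform
        a, _ = register(fixed, moving, roi, init, cfg)
        b, _ = register(fixed, moving, roi, init, cfg)
        assert np.array_equal(a.rotation, b.rotation)
        assert np.array_equal(a.translation, b.translation)

    def test_roi_centroid_is_mask_mean(self):
        data = np.zeros((5, 5, 5), bool)
        data[1, 2, 3] = data[3, 2, 1] = True
        mask = BinaryMask(data, (2.0, 2.0, 2.0), origin=(1.0, 0.0, 0.0))
        assert np.allclose(roi_centroid(mask), (5.0, 4.0, 4.0))
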