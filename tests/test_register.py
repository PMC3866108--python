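import numpy as np
import pytest

from neoseg.imaging import VolumeImage
from neoseg.phantom import PhantomSpec, make_subject
from neoseg.register import (
    AffineTransform,
    RegistrationOptions,
    build_atlas,
    invert,
    register_affine,
    resample,
    to_atlas_coords,
)


@pytest.fixture(scope="module")
def reg_subject():
    spec = PhantomSpec(shift_mm=0.0, rot_deg=0.0, noise_sd=3.0, bias_amplitude=0.0)
    return make_subject(spec, 1)


def _rotation_z(deg: float, translation=(0.0, 0.0, 0.0)) -> AffineTransform:
    th = np.deg2rad(deg)
    m = np.eye(4)
    m[:2, :2] = [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
    m[:3, 3] = translation
    return AffineTransform(m)


class TestAffineTransform:
    def test_invert_identity_and_translation(self):
        assert np.allclose(invert(AffineTransform.identity()).matrix, np.eye(4))
        t = AffineTransform.from_translation([1.5, -2.0, 3.0])
        np.testing.assert_allclose(invert(t).translation, [-1.5, 2.0, -3.0])

    def test_invert_roundtrip_on_random_points(self, rng):
        m = np.eye(4)
        m[:3, :3] = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
        m[:3, 3] = rng.normal(scale=5, size=3)
        t = AffineTransform(m)
        pts = rng.normal(scale=50, size=(100, 3))
        back = invert(t).apply(t.apply(pts))
        assert np.abs(back - pts).max() < 1e-6

    def test_singular_matrix_rejected(self):
        m = np.eye(4)
        m[0, 0] = 0.0
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(m)


class TestResample:
    def test_identity_preserves_data(self, reg_subject):
        out = resample(reg_subject.t2, AffineTransform.identity(), reg_subject.t2)
        np.testing.assert_allclose(out.data, reg_subject.t2.data, atol=1e-4)

    def test_integer_voxel_translation_nearest_matches_array_shift(self, reg_subject):
        # +2 voxels along x at 1 mm spacing = +2 mm world shift of the
        # sampling points; oracle is a plain array roll
        t = AffineTransform.from_translation([2.0, 0.0, 0.0])
        labels_vol = VolumeImage(reg_subject.labels.data.astype(np.float32), reg_subject.labels.affine)
        out = resample(labels_vol, t, reg_subject.t2, interp="nearest")
        expected = np.zeros_like(reg_subject.labels.data, dtype=np.float32)
        expected[:-2] = reg_subject.labels.data[2:]
        np.testing.assert_array_equal(out.data, expected)

    def test_linear_interpolation_keeps_probabilities_in_unit_interval(self, reg_subject, rng):
        probs = rng.uniform(size=reg_subject.t2.shape).astype(np.float32)
        vol = VolumeImage(probs, reg_subject.t2.affine)
        out = resample(vol, _rotation_z(3.0, (0.5, -0.25, 0.4)), reg_subject.t2)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_bad_interp_rejected(self, reg_subject):
        with pytest.raises(ValueError, match="interp"):
            resample(reg_subject.t2, AffineTransform.identity(), reg_subject.t2, interp="cubic")


class TestRegisterAffine:
    def test_self_registration_is_near_identity(self, reg_subject):
        t = register_affine(reg_subject.t2, reg_subject.t2)
        assert np.abs(t.translation).max() < 0.1  # < 0.1 voxel at 1 mm
        assert np.abs(t.matrix[:3, :3] - np.eye(3)).max() < 0.01

    def test_known_translation_recovered_within_half_mm(self, reg_subject):
        shift = np.array([3.0, -2.0, 1.0])
        moved = resample(reg_subject.t2, AffineTransform.from_translation(shift), reg_subject.t2)
        t = register_affine(reg_subject.t2, moved)
        # ideal transform maps fixed points through the inverse shift
        np.testing.assert_allclose(t.translation, -shift, atol=0.5)

    def test_known_rotation_recovered_within_one_degree(self, reg_subject):
        moved = resample(reg_subject.t2, _rotation_z(5.0), reg_subject.t2)
        t = register_affine(reg_subject.t2, moved)
        u, _, vt = np.linalg.svd(t.matrix[:3, :3])
        angle = np.rad2deg(np.arctan2((u @ vt)[1, 0], (u @ vt)[0, 0]))
        assert angle == pytest.approx(-5.0, abs=1.0)

    def test_registration_increases_mutual_information(self, reg_subject):
        from sklearn.metrics import mutual_info_score

        shift = AffineTransform.from_translation([3.0, 2.0, -1.0])
        moved = resample(reg_subject.t2, shift, reg_subject.t2)
        t = register_affine(reg_subject.t2, moved)
        aligned = resample(moved, t, reg_subject.t2)

        def mi(a, b):
            ha = np.digitize(a.ravel(), np.histogram_bin_edges(a, 32))
            hb = np.digitize(b.ravel(), np.histogram_bin_edges(b, 32))
            return mutual_info_score(ha, hb)

        assert mi(reg_subject.t2.data, aligned.data) > mi(reg_subject.t2.data, moved.data)

    def test_constant_image_rejected(self, reg_subject):
        flat = VolumeImage(np.zeros_like(reg_subject.t2.data), reg_subject.t2.affine)
        with pytest.raises(ValueError, match="constant"):
            register_affine(flat, reg_subject.t2)


class TestBuildAtlas:
    def test_identical_inputs_converge_to_input_in_one_iteration(self, reg_subject):
        vols = [reg_subject.t2] * 3
        res = build_atlas(vols, max_iter=3)
        assert res.iterations_run == 1
        # equal up to the sub-voxel interpolation of the near-identity
        # self-registration: mean absolute difference under 1% of range
        diff = np.mean(np.abs(res.atlas.data.astype(float) - reg_subject.t2.data))
        assert diff < 0.01 * np.ptp(reg_subject.t2.data)
        for t in res.transforms:
            assert np.abs(t.translation).max() < 0.2

    def test_max_iter_zero_returns_plain_mean(self, reg_subject, rng):
        other = VolumeImage(reg_subject.t2.data + rng.normal(scale=1.0, size=reg_subject.t2.shape).astype(np.float32),
                            reg_subject.t2.affine)
        res = build_atlas([reg_subject.t2, other], max_iter=0)
        assert res.iterations_run == 0
        np.testing.assert_allclose(
            res.atlas.data, (reg_subject.t2.data.astype(np.float64) + other.data) / 2, atol=1e-3
        )

    def test_shifted_cohort_atlas_is_sharper_than_plain_mean(self):
        spec = PhantomSpec(shift_mm=2.0, rot_deg=0.0, noise_sd=3.0, class_sd=2.0,
                           bias_amplitude=0.0, shape=(64, 64, 32), spacing=(1.5, 1.5, 3.0))
        vols = [make_subject(spec, s).t2 for s in range(5)]
        plain = build_atlas(vols, max_iter=0)
        refined = build_atlas(vols, max_iter=2)

        def gradient_energy(v):
            g = np.gradient(np.asarray(v.data, dtype=float))
            return float(sum((gi ** 2).sum() for gi in g))

        assert gradient_energy(refined.atlas) > gradient_energy(plain.atlas)

    def test_fewer_than_two_subjects_rejected(self, reg_subject):
        with pytest.raises(ValueError, match="at least 2"):
            build_atlas([reg_subject.t2])


def test_to_atlas_coords_of_atlas_itself_is_identity(reg_subject):
    t = to_atlas_coords(reg_subject.t2, reg_subject.t2)
    assert np.abs(t.translation).max() < 0.1
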