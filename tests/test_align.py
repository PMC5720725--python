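import numpy as np
import pytest

from toothssm.align import (RigidTransform, align_chain, bbox_scale,
                            coarse_transform, icp, origin_align)
from toothssm.errors import InvalidInputError
from toothssm.primitives import make_icosphere
from toothssm.synth import ToothParams, generate_tooth


@pytest.fixture(scope="module")
def tooth_mesh():
    mesh, _ = generate_tooth(ToothParams(mesh_resolution=(24, 28)))
    return mesh


@pytest.fixture(scope="module")
def blob():
    """Asymmetric coarse test solid (wide ICP capture range)."""
    sph = make_icosphere(4.0, 1)
    rng = np.random.default_rng(11)
    v = sph.vertices
    coef = rng.normal(size=(3, 3))
    r = 1 + 0.3 * np.tanh((v / 4.0) @ coef[0]) + 0.25 * np.sin((v / 4.0) @ coef[1] * 1.5)
    return sph.with_vertices(v * r[:, None])


# ------------------------------------------------------------ quaternion oracle

def _quat_axis(axis, angle):
    h = angle / 2.0
    q = np.zeros(4)
    q[0] = np.cos(h)
    q[1 + axis] = np.sin(h)
    return q


def _quat_mul(a, b):
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _quat_matrix(q):
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


class TestBboxScale:
    def test_identity(self, tooth_mesh):
        _, s = bbox_scale(tooth_mesh, tooth_mesh)
        assert np.allclose(s.as_array(), 1.0)

    def test_uniform_double(self, tooth_mesh):
        target = tooth_mesh.with_vertices(tooth_mesh.vertices * 2.0)
        scaled, s = bbox_scale(tooth_mesh, target)
        assert np.allclose(s.as_array(), 2.0)
        ext_s = scaled.vertices.max(0) - scaled.vertices.min(0)
        ext_t = target.vertices.max(0) - target.vertices.min(0)
        assert np.allclose(ext_s, ext_t, rtol=1e-9)

    def test_single_axis_stretch(self, tooth_mesh):
        target = tooth_mesh.with_vertices(tooth_mesh.vertices * np.array([1, 1, 1.5]))
        scaled, s = bbox_scale(tooth_mesh, target)
        assert np.allclose(s.as_array(), [1, 1, 1.5])
        ext_s = scaled.vertices.max(0) - scaled.vertices.min(0)
        ext_t = target.vertices.max(0) - target.vertices.min(0)
        assert np.allclose(ext_s, ext_t, rtol=1e-9)

    def test_zero_extent_rejected(self, tooth_mesh):
        flat = tooth_mesh.with_vertices(tooth_mesh.vertices * np.array([1, 1, 0.0]))
        with pytest.raises(InvalidInputError):
            bbox_scale(flat, tooth_mesh)


class TestOriginAlign:
    def test_identity(self, tooth_mesh):
        t = origin_align(tooth_mesh, tooth_mesh)
        assert np.allclose(t.translation, 0)
        assert np.allclose(t.rotation, np.eye(3))

    def test_known_shift(self, tooth_mesh):
        target = tooth_mesh.with_vertices(tooth_mesh.vertices + np.array([1, 2, 3.0]))
        t = origin_align(tooth_mesh, target)
        assert np.allclose(t.translation, [1, 2, 3])

    def test_centroids_coincide(self, blob, tooth_mesh):
        t = origin_align(blob, tooth_mesh)
        moved = t.apply_mesh(blob)
        assert np.allclose(moved.centroid(), tooth_mesh.centroid(), atol=1e-12)


class TestCoarseTransform:
    def test_zero_is_identity(self):
        t = coarse_transform((0, 0, 0), (0, 0, 0))
        assert np.allclose(t.rotation, np.eye(3))
        assert np.allclose(t.translation, 0)

    def test_pi_involution(self):
        t = coarse_transform((np.pi, 0, 0), (0, 0, 0))
        twice = t.compose(t)
        assert np.allclose(twice.rotation, np.eye(3), atol=1e-12)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b, c = rng.uniform(-np.pi, np.pi, 3)
            t = coarse_transform((a, b, c), (0, 0, 0))
            # intrinsic Z-Y-X == q_z * q_y * q_x
            q = _quat_mul(_quat_mul(_quat_axis(2, a), _quat_axis(1, b)), _quat_axis(0, c))
            assert np.allclose(t.rotation, _quat_matrix(q), atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            coarse_transform((np.nan, 0, 0), (0, 0, 0))


class TestRigidTransform:
    def test_inverse_composition_is_identity(self):
        rng = np.random.default_rng(5)
        t = coarse_transform(rng.uniform(-np.pi, np.pi, 3), rng.normal(size=3))
        ident = t.compose(t.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(ident.translation, 0, atol=1e-12)

    def test_matrix_round_trip(self):
        t = coarse_transform((0.3, -0.2, 0.9), (1, 2, 3))
        again = RigidTransform.from_matrix(t.to_matrix())
        assert np.allclose(again.rotation, t.rotation)
        assert np.allclose(again.translation, t.translation)

    def test_improper_rotation_rejected(self):
        with pytest.raises(InvalidInputError):
            RigidTransform(np.diag([1, 1, -1.0]), np.zeros(3))


class TestICP:
    def test_identity_target(self, blob):
        res = icp(blob, blob)
        assert res.rms == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_transform(self, blob):
        truth = coarse_transform((np.radians(10), 0, 0), (1.0, -2.0, 0.5))
        target = truth.apply_mesh(blob)
        res = icp(blob, target)
        assert res.rms < 1e-6
        assert np.allclose(res.transform.rotation, truth.rotation, atol=1e-6)
        assert np.allclose(res.transform.translation, truth.translation, atol=1e-6)

    def test_rms_trace_monotone_nonincreasing(self, blob, tooth_mesh):
        shift = origin_align(tooth_mesh, blob)
        res = icp(shift.apply_mesh(tooth_mesh), blob)
        trace = np.asarray(res.rms_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_nan_input_rejected(self, blob):
        bad = blob.copy()
        bad.vertices[0, 0] = np.nan
        with pytest.raises(InvalidInputError):
            icp(bad, blob)


class TestAlignChain:
    @pytest.mark.parametrize("deg", [10, 20, 30])
    def test_recovers_scaled_rotated_translated_copy(self, blob, deg):
        angles = (np.radians(deg), np.radians(0.7 * deg), np.radians(-0.5 * deg))
        rot = coarse_transform(angles, (0, 0, 0))
        target = rot.apply_mesh(blob)
        target = target.with_vertices(target.vertices * 1.3 + np.array([4.0, -2.0, 7.0]))
        # the known rotation is supplied as the programmatic coarse transform
        res = align_chain(blob, target, coarse=rot)
        rms = np.sqrt(np.mean(np.sum((res.aligned.vertices - target.vertices) ** 2, axis=1)))
        assert rms < 1e-4
        assert np.allclose(res.scale.as_array(), 1.3, rtol=1e-9)

    @pytest.mark.parametrize("deg", [10, 20])
    def test_origin_plus_icp_recovers_moderate_rotations(self, blob, deg):
        # no scaling applied, so the bbox stage is skipped: origin + ICP
        # alone must recover moderate rotations within the capture range
        rot = coarse_transform((np.radians(deg), 0, 0), (3.0, 1.0, -2.0))
        target = rot.apply_mesh(blob)
        shift = origin_align(blob, target)
        res = icp(shift.apply_mesh(blob), target)
        final = res.transform.apply_mesh(shift.apply_mesh(blob))
        rms = np.sqrt(np.mean(np.sum((final.vertices - target.vertices) ** 2, axis=1)))
        assert rms < 1e-4
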