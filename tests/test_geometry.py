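import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marmoreg.errors import DegenerateGeometryError, FormatError, InputError
from marmoreg.geometry import (
    EulerAngles,
    PointSet,
    RigidTransform,
    dedrift,
    euler_compose,
    euler_decompose,
    kabsch_fit,
    mean_transform,
    point_to_line_distance,
    read_transform,
    write_transform,
)

QUAD = PointSet(["a", "b", "c", "d"],
                np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]]))


def random_transform(rng, max_deg=15.0, max_mm=5.0) -> RigidTransform:
    return RigidTransform.from_euler_translation(
        rng.uniform(-max_deg, max_deg, 3), rng.uniform(-max_mm, max_mm, 3))


# ---------------------------------------------------------------- kabsch

def horn_quaternion_fit(source: PointSet, target: PointSet) -> RigidTransform:
    """Independent SVD-free oracle: Horn's closed-form quaternion solution."""
    p = source.coords - source.coords.mean(axis=0)
    q = target.reordered(source.labels).coords
    qc = q.mean(axis=0)
    q = q - qc
    s = p.T @ q
    n = np.array([
        [s[0, 0] + s[1, 1] + s[2, 2], s[1, 2] - s[2, 1], s[2, 0] - s[0, 2], s[0, 1] - s[1, 0]],
        [s[1, 2] - s[2, 1], s[0, 0] - s[1, 1] - s[2, 2], s[0, 1] + s[1, 0], s[2, 0] + s[0, 2]],
        [s[2, 0] - s[0, 2], s[0, 1] + s[1, 0], -s[0, 0] + s[1, 1] - s[2, 2], s[1, 2] + s[2, 1]],
        [s[0, 1] - s[1, 0], s[2, 0] + s[0, 2], s[1, 2] + s[2, 1], -s[0, 0] - s[1, 1] + s[2, 2]],
    ])
    w, v = np.linalg.eigh(n)
    a, b, c, d = v[:, -1]  # unit quaternion of the max eigenvalue
    rot = np.array([
        [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
        [2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)],
        [2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d],
    ])
    return RigidTransform(rot, qc - rot @ source.coords.mean(axis=0))


def test_kabsch_identity_on_identical_sets():
    t = kabsch_fit(QUAD, QUAD)
    assert t.is_close(RigidTransform.identity(), 1e-9)
    assert np.linalg.norm(t.apply(QUAD.coords) - QUAD.coords) < 1e-9


def test_kabsch_recovers_generating_transform():
    true = RigidTransform.from_euler_translation((10.0, 0, 0), (1.0, 2.0, 3.0))
    fitted = kabsch_fit(QUAD, QUAD.transformed(true))
    assert fitted.is_close(true, 1e-9)


def test_kabsch_noiseless_residual_below_1e9(rng):
    for _ in range(10):
        pts = PointSet(list("abcdef"), rng.uniform(-20, 20, (6, 3)))
        true = random_transform(rng)
        fitted = kabsch_fit(pts, pts.transformed(true))
        residual = np.linalg.norm(
            fitted.apply(pts.coords) - true.apply(pts.coords), axis=1)
        assert residual.max() < 1e-9


def test_kabsch_matches_horn_quaternion_oracle(rng):
    for n in (4, 5, 6, 8):
        src = PointSet([f"p{i}" for i in range(n)], rng.uniform(-20, 20, (n, 3)))
        tgt = PointSet(src.labels,
                       random_transform(rng).apply(src.coords) + rng.normal(0, 0.5, (n, 3)))
        ours = kabsch_fit(src, tgt)
        oracle = horn_quaternion_fit(src, tgt)
        assert np.abs(ours.rotation - oracle.rotation).max() < 1e-6
        assert np.abs(ours.translation - oracle.translation).max() < 1e-6


def test_kabsch_beats_small_angle_grid_search(rng):
    """Coarse exhaustive search over rotations cannot beat the closed form."""
    src = PointSet(list("abcde"), rng.uniform(-15, 15, (5, 3)))
    true = RigidTransform.from_euler_translation((2.0, -3.0, 1.5), (1, -1, 2))
    tgt = PointSet(src.labels, true.apply(src.coords) + rng.normal(0, 0.3, (5, 3)))
    fitted = kabsch_fit(src, tgt)

    def cost(rot):
        translation = tgt.coords.mean(0) - rot @ src.coords.mean(0)
        return np.sum((src.coords @ rot.T + translation - tgt.coords) ** 2)

    best = min(
        (cost(euler_compose((p, r, y)))
         for p in np.arange(-6, 6.1, 0.5)
         for r in np.arange(-6, 6.1, 0.5)
         for y in np.arange(-6, 6.1, 0.5)),
    )
    assert cost(fitted.rotation) <= best + 1e-12


def test_kabsch_errors():
    with pytest.raises(InputError):
        kabsch_fit(QUAD, PointSet(["a", "b", "c", "x"], QUAD.coords))
    line = PointSet(["a", "b", "c"], np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2]]))
    with pytest.raises(DegenerateGeometryError):
        kabsch_fit(line, line)
    two = PointSet(["a", "b"], np.array([[0.0, 0, 0], [1, 0, 0]]))
    with pytest.raises(DegenerateGeometryError):
        kabsch_fit(two, two)


# ---------------------------------------------------------------- euler

def test_euler_identity():
    e = euler_decompose(RigidTransform.identity())
    assert e.as_tuple() == (0.0, 0.0, 0.0)
    assert not e.gimbal_warning


@pytest.mark.parametrize("angles", [(10.0, 0.6, 0.2), (-3.0, 0.0, 0.0),
                                    (0.0, 45.0, 0.0), (12.0, -7.0, 33.0)])
def test_euler_round_trip(angles):
    e = euler_decompose(euler_compose(angles))
    assert np.abs(np.array(e.as_tuple()) - angles).max() < 1e-6


def test_euler_matches_scipy_convention(rng):
    from scipy.spatial.transform import Rotation

    for _ in range(20):
        angles = rng.uniform(-60, 60, 3)
        ours = euler_compose(angles)
        scipys = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
        assert np.abs(ours - scipys).max() < 1e-12


@settings(max_examples=100, deadline=None)
@given(pitch=st.floats(-179, 179), roll=st.floats(-80, 80), yaw=st.floats(-179, 179))
def test_euler_round_trip_property(pitch, roll, yaw):
    e = euler_decompose(euler_compose((pitch, roll, yaw)))
    back = euler_compose(e.as_tuple())
    assert np.abs(back - euler_compose((pitch, roll, yaw))).max() < 1e-9


def test_euler_gimbal_warning():
    e = euler_decompose(euler_compose((10.0, 89.9, 5.0)))
    assert e.gimbal_warning
    # rotation still reproduced even at the flagged pose
    assert np.abs(euler_compose(e.as_tuple()) - euler_compose((10.0, 89.9, 5.0))).max() < 1e-9


# ---------------------------------------------------------------- mean / dedrift

def test_mean_single_transform(rng):
    t = random_transform(rng)
    assert mean_transform([t]).is_close(t, 1e-9)


def test_mean_symmetric_pair_is_identity():
    plus = RigidTransform.from_euler_translation((5.0, 0, 0))
    minus = RigidTransform.from_euler_translation((-5.0, 0, 0))
    assert mean_transform([plus, minus]).is_close(RigidTransform.identity(), 1e-9)


def test_mean_fixed_point_property(rng):
    ts = [random_transform(rng) for _ in range(20)]
    centred = dedrift(ts)
    assert mean_transform(centred).is_close(RigidTransform.identity(), 1e-9)


def test_mean_empty_list_errors():
    with pytest.raises(InputError):
        mean_transform([])
    with pytest.raises(InputError):
        dedrift([])


def test_dedrift_single():
    t = RigidTransform.from_euler_translation((4.0, 1.0, -2.0), (3, 2, 1))
    (out,) = dedrift([t])
    assert out.is_close(RigidTransform.identity(), 1e-9)


def test_dedrift_removes_z_drift(rng):
    base = RigidTransform.from_euler_translation((0, 0, 4.0))
    ts = [base.compose(random_transform(rng, 2, 1)) for _ in range(10)]
    out = dedrift(ts)
    mean = mean_transform(out)
    assert np.rad2deg(np.linalg.norm(mean.rotation_vector())) < 1e-9


def test_dedrift_idempotent(rng):
    ts = dedrift([random_transform(rng) for _ in range(8)])
    again = dedrift(ts)
    for a, b in zip(ts, again):
        assert a.is_close(b, 1e-9)


# ---------------------------------------------------------------- point to line

def test_point_on_line_distance_zero():
    assert point_to_line_distance((2, 2, 2), (0, 0, 0), (1, 1, 1)) < 1e-12


def test_point_to_line_unit_case():
    assert point_to_line_distance((1, 0, 0), (0, 0, 0), (0, 0, 1)) == pytest.approx(1.0)


def test_point_to_line_rigid_invariance(rng):
    for _ in range(20):
        p, lp = rng.uniform(-10, 10, 3), rng.uniform(-10, 10, 3)
        d = rng.uniform(-1, 1, 3)
        if np.linalg.norm(d) < 1e-3:
            continue
        t = random_transform(rng)
        before = point_to_line_distance(p, lp, d)
        after = point_to_line_distance(t.apply(p), t.apply(lp), t.rotation @ d)
        assert before == pytest.approx(after, abs=1e-9)


def test_point_to_line_zero_direction():
    with pytest.raises(InputError):
        point_to_line_distance((1, 0, 0), (0, 0, 0), (0, 0, 0))


# ---------------------------------------------------------------- types & files

def test_rigid_transform_invariants(rng):
    t = random_transform(rng)
    assert np.abs(t.rotation @ t.rotation.T - np.eye(3)).max() < 1e-9
    assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)
    assert t.compose(t.inverse()).is_close(RigidTransform.identity(), 1e-9)
    pts = rng.uniform(-10, 10, (6, 3))
    before = np.linalg.norm(pts[:, None] - pts[None], axis=2)
    moved = t.apply(pts)
    after = np.linalg.norm(moved[:, None] - moved[None], axis=2)
    assert np.abs(before - after).max() < 1e-9


def test_rejects_improper_rotation():
    with pytest.raises(InputError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
    with pytest.raises(InputError):
        RigidTransform(np.eye(3) * 2.0, np.zeros(3))


def test_pointset_validation():
    with pytest.raises(InputError):
        PointSet(["a", "a"], np.zeros((2, 3)))
    with pytest.raises(InputError):
        PointSet(["a"], [[np.nan, 0, 0]])
    with pytest.raises(InputError):
        PointSet([], np.zeros((0, 3)))


@pytest.mark.parametrize("suffix", [".mat", ".json"])
def test_transform_file_round_trip(tmp_path, rng, suffix):
    t = random_transform(rng)
    path = tmp_path / f"xfm{suffix}"
    write_transform(t, path)
    assert read_transform(path).is_close(t, 1e-9)


def test_transform_file_errors(tmp_path):
    bad = tmp_path / "bad.mat"
    bad.write_text("1 0 0\n0 1 0\n")
    with pytest.raises(FormatError):
        read_transform(bad)
    scaled = tmp_path / "scaled.mat"
    np.savetxt(scaled, np.diag([2.0, 1.0, 1.0, 1.0]))
    with pytest.raises(FormatError):
        read_transform(scaled)
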