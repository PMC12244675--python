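import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from activegaze.geometry import (
    cancellation,
    decompose_saccade,
    euler_to_quat,
    eye_contribution,
    eye_in_world,
    head_euler,
    relative_elevation,
    standing_height,
)


class FakeFix:
    def __init__(self, eye, quat):
        self.mean_eye_in_head = np.asarray(eye, float)
        self.mean_head_orientation = np.asarray(quat, float)


def _quat_to_matrix(q):
    """Hand-rolled quaternion (x, y, z, w) to rotation matrix — oracle."""
    x, y, z, w = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def test_eye_in_world_identity():
    q = np.array([0.0, 0.0, 0.0, 1.0])
    v = np.array([1.0, 0.0, 0.0])
    np.testing.assert_allclose(eye_in_world(q, v), v, atol=1e-15)


def test_eye_in_world_90deg_yaw():
    q = euler_to_quat(0.0, 0.0, 90.0)
    out = eye_in_world(q, [1.0, 0.0, 0.0])
    np.testing.assert_allclose(out, [0.0, 1.0, 0.0], atol=1e-12)


def test_eye_in_world_matches_matrix_oracle(rng):
    for _ in range(100):
        q = Rotation.random(random_state=rng).as_quat()
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        np.testing.assert_allclose(
            eye_in_world(q, v), _quat_to_matrix(q) @ v, atol=1e-12
        )


def test_decompose_eye_only_shift():
    q = euler_to_quat(0.0, 0.0, 0.0)
    a = FakeFix([1.0, 0.0, 0.0], q)
    b = FakeFix([np.cos(np.radians(10)), np.sin(np.radians(10)), 0.0], q)
    d = decompose_saccade(a, b)
    assert d.eye_in_head_amp == pytest.approx(10.0, abs=1e-9)
    assert d.head_amp == pytest.approx(0.0, abs=1e-9)
    assert d.eye_in_world_amp == pytest.approx(10.0, abs=1e-9)
    assert d.eye_contribution == pytest.approx(1.0)
    assert d.head_minimal and not d.head_dominant


def test_decompose_perfect_compensation():
    # head yaws +20 deg while the eye counter-rotates -20: gaze is stable
    q_a = euler_to_quat(0.0, 0.0, 0.0)
    q_b = euler_to_quat(0.0, 0.0, 20.0)
    eye_b = Rotation.from_quat(q_b).inv().apply([1.0, 0.0, 0.0])
    a = FakeFix([1.0, 0.0, 0.0], q_a)
    b = FakeFix(eye_b, q_b)
    d = decompose_saccade(a, b)
    assert d.eye_in_world_amp == pytest.approx(0.0, abs=1e-9)
    assert d.eye_in_head_amp == pytest.approx(20.0, abs=1e-9)
    assert d.head_amp == pytest.approx(20.0, abs=1e-9)
    assert d.cancels


def test_decompose_matches_arccos_oracle(rng):
    for _ in range(200):
        a = FakeFix(_rand_dir(rng), Rotation.random(random_state=rng).as_quat())
        b = FakeFix(_rand_dir(rng), Rotation.random(random_state=rng).as_quat())
        d = decompose_saccade(a, b)
        assert d.eye_in_head_amp == pytest.approx(
            _arccos_angle(a.mean_eye_in_head, b.mean_eye_in_head), abs=1e-9
        )
        fa = _quat_to_matrix(a.mean_head_orientation) @ [1, 0, 0]
        fb = _quat_to_matrix(b.mean_head_orientation) @ [1, 0, 0]
        assert d.head_amp == pytest.approx(_arccos_angle(fa, fb), abs=1e-9)
        wa = _quat_to_matrix(a.mean_head_orientation) @ a.mean_eye_in_head
        wb = _quat_to_matrix(b.mean_head_orientation) @ b.mean_eye_in_head
        assert d.eye_in_world_amp == pytest.approx(_arccos_angle(wa, wb), abs=1e-9)


def _rand_dir(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _arccos_angle(u, v):
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


@pytest.mark.parametrize(
    "eye,head,expected",
    [((10.0, 10.0), None, 0.5), ((10.0, 0.0), None, 1.0), ((5.0, 15.0), None, 0.25)],
)
def test_eye_contribution_values(eye, head, expected):
    assert eye_contribution(*eye) == pytest.approx(expected)


def test_eye_contribution_undefined_for_no_movement():
    assert eye_contribution(0.0, 0.0) is None


@pytest.mark.parametrize(
    "eye_az,head_az,expected",
    [(10.0, -5.0, True), (10.0, 10.0, False), (0.0, -5.0, False)],
)
def test_cancellation_sign_rule(eye_az, head_az, expected):
    q_a = euler_to_quat(0.0, 0.0, 0.0)
    q_b = euler_to_quat(0.0, 0.0, head_az)
    a = FakeFix([1.0, 0.0, 0.0], q_a)
    eye_b = [np.cos(np.radians(eye_az)), np.sin(np.radians(eye_az)), 0.0]
    b = FakeFix(eye_b, q_b)
    assert cancellation(a, b) is expected


def test_head_euler_canonical_and_yaw():
    e = head_euler(np.array([0.0, 0.0, 0.0, 1.0]))
    assert (e.roll, e.pitch, e.yaw) == (0.0, 0.0, 0.0)
    e = head_euler(euler_to_quat(0.0, 0.0, 90.0))
    assert e.yaw == pytest.approx(90.0, abs=1e-9)
    assert e.roll == pytest.approx(0.0, abs=1e-9)
    assert e.pitch == pytest.approx(0.0, abs=1e-9)


def test_head_euler_sign_conventions():
    # tilting the head down must give negative pitch
    down = euler_to_quat(0.0, -20.0, 0.0)
    fwd = Rotation.from_quat(down).apply([1.0, 0.0, 0.0])
    assert fwd[2] < 0  # forward axis points below the horizon
    assert head_euler(down).pitch == pytest.approx(-20.0, abs=1e-9)
    # positive roll tilts to the wearer's right (left ear up)
    right = euler_to_quat(15.0, 0.0, 0.0)
    left_ear = Rotation.from_quat(right).apply([0.0, 1.0, 0.0])
    assert left_ear[2] > 0
    assert head_euler(right).roll == pytest.approx(15.0, abs=1e-9)


def test_euler_round_trip_random(rng):
    for _ in range(300):
        q = Rotation.random(random_state=rng).as_quat()
        e = head_euler(q)
        if e.gimbal:
            continue
        back = euler_to_quat(e.roll, e.pitch, e.yaw)
        # q and -q are the same rotation
        assert min(np.abs(back - q).max(), np.abs(back + q).max()) < 1e-9


def test_frame_equivariance(rng):
    """Rotating the whole world leaves every amplitude unchanged."""
    world = Rotation.random(random_state=rng)
    for _ in range(50):
        qa = Rotation.random(random_state=rng)
        qb = Rotation.random(random_state=rng)
        ea, eb = _rand_dir(rng), _rand_dir(rng)
        d1 = decompose_saccade(FakeFix(ea, qa.as_quat()), FakeFix(eb, qb.as_quat()))
        d2 = decompose_saccade(
            FakeFix(ea, (world * qa).as_quat()), FakeFix(eb, (world * qb).as_quat())
        )
        assert d1.eye_in_head_amp == pytest.approx(d2.eye_in_head_amp, abs=1e-9)
        assert d1.head_amp == pytest.approx(d2.head_amp, abs=1e-9)
        assert d1.eye_in_world_amp == pytest.approx(d2.eye_in_world_amp, abs=1e-9)


def test_triangle_bound_against_rotation_angle(rng):
    """The world amplitude never exceeds eye amplitude plus the geodesic
    angle of the head rotation (the forward-axis displacement alone can
    understate a head rotation with a twist component)."""
    for _ in range(200):
        qa = Rotation.random(random_state=rng)
        qb = Rotation.random(random_state=rng)
        a = FakeFix(_rand_dir(rng), qa.as_quat())
        b = FakeFix(_rand_dir(rng), qb.as_quat())
        d = decompose_saccade(a, b)
        rot_angle = np.degrees((qb * qa.inv()).magnitude())
        assert d.eye_in_world_amp <= d.eye_in_head_amp + rot_angle + 1e-9


def test_rotation_angle_bound_on_scripted_saccades(clean_run):
    from activegaze.geometry import _as_rotation

    for s, (fa, fb) in zip(
        clean_run["saccades"],
        zip(clean_run["fixations"][:-1], clean_run["fixations"][1:]),
    ):
        d = s.decomposition
        rot = _as_rotation(fb.mean_head_orientation) * _as_rotation(fa.mean_head_orientation).inv()
        assert d.eye_in_world_amp <= d.eye_in_head_amp + np.degrees(rot.magnitude()) + 1e-6


def test_standing_height_and_relative_elevation():
    z = np.full(500, 1.7)
    assert standing_height(z) == pytest.approx(1.7)
    np.testing.assert_allclose(relative_elevation(z[:3], 1.7), 0.0)
    crouch = z.copy()
    crouch[100] = 1.2
    assert relative_elevation(1.2, standing_height(crouch)) == pytest.approx(-0.5)


def test_standing_height_removes_mocap_spikes():
    z = np.concatenate([np.full(300, 1.70) + np.linspace(0, 0.01, 300), [2.5, 2.5]])
    # the 2.5 m spikes are > 3 SD and must not define the standing height
    assert standing_height(z) < 1.75
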