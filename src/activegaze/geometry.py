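"""Gaze and head-pose geometry.

Conventions
-----------
* World frame: right-handed, z-up; x-y is the arena floor.
* Head orientation: unit quaternion in scipy scalar-last order
  ``(qx, qy, qz, qw)``; the head's forward axis defaults to local +x.
* Eye-in-head gaze: unit vector in the head frame (+x straight ahead,
  +y to the wearer's left, +z up).
* Angles cross the API in degrees; internal math is in radians.

The central operation is the decomposition of a gaze shift between two
fixations into its eye-in-head, head-in-world and eye-in-world amplitudes:
the eye amplitude is the angle between the mean eye-in-head directions, the
head amplitude the angle between the world-frame head forward axes, and the
world amplitude the angle between the two eye-in-world vectors (head
rotation applied to the eye direction).  Eye and head rotations may add or
cancel, so the world amplitude can be anywhere between 0 and the sum of the
two components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ._util import angle_between_deg, normalize, sd_outlier_mask, wrap_deg

__all__ = [
    "EulerAngles",
    "AmplitudeDecomposition",
    "DEFAULT_FORWARD_AXIS",
    "eye_in_world",
    "head_forward",
    "decompose_saccade",
    "eye_contribution",
    "cancellation",
    "head_euler",
    "euler_to_quat",
    "azimuth_deg",
    "standing_height",
    "relative_elevation",
]

#: head-marker forward axis in the rigid-body frame.  Mocap marker mounts
#: are arbitrary, so recording adapters may supply a calibrated axis; the
#: simulator uses +x.
DEFAULT_FORWARD_AXIS = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class EulerAngles:
    """Head attitude as intrinsic yaw (pan) -> pitch (flexion) -> roll
    (lateral bend), degrees.  Negative pitch tilts the head down; positive
    roll tilts it to the wearer's right.  ``gimbal`` flags |pitch| = 90
    configurations where yaw and roll are split by the roll := 0 convention.
    """

    roll: float
    pitch: float
    yaw: float
    gimbal: bool = False


@dataclass(frozen=True)
class AmplitudeDecomposition:
    """Eye/head split of one gaze shift, all amplitudes in degrees."""

    eye_in_head_amp: float
    head_amp: float
    eye_in_world_amp: float
    eye_contribution: float | None
    head_dominant: bool
    cancels: bool
    head_minimal: bool

    def __post_init__(self) -> None:
        for a in (self.eye_in_head_amp, self.head_amp, self.eye_in_world_amp):
            if not (-1e-9 <= a <= 180.0 + 1e-9):
                raise ValueError(f"amplitude {a} outside [0, 180]")


def _as_rotation(orientation) -> Rotation:
    if isinstance(orientation, Rotation):
        return orientation
    return Rotation.from_quat(np.asarray(orientation, dtype=float))


def eye_in_world(head_orientation, eye_in_head: np.ndarray) -> np.ndarray:
    """Rotate a head-frame gaze direction into the world frame."""
    e = normalize(np.asarray(eye_in_head, dtype=float))
    return _as_rotation(head_orientation).apply(e)


def head_forward(head_orientation, forward_axis: np.ndarray = DEFAULT_FORWARD_AXIS) -> np.ndarray:
    """World-frame direction of the head's forward axis."""
    return _as_rotation(head_orientation).apply(normalize(forward_axis))


def eye_contribution(eye_amp: float, head_amp: float) -> float | None:
    """Additive share of the eye in a gaze shift: eye / (eye + head).

    With this definition "the head contributed more" is exactly
    head_amp > eye_amp, i.e. eye_contribution < 0.5.  Returns ``None``
    when both amplitudes are zero (no movement; excluded from aggregates).
    """
    total = eye_amp + head_amp
    if total <= 0.0:
        return None
    return eye_amp / total


def azimuth_deg(direction: np.ndarray) -> float:
    """Horizontal-plane bearing of a direction vector, degrees in
    (-180, 180], measured from +x toward +y."""
    d = np.asarray(direction, dtype=float)
    return float(np.degrees(np.arctan2(d[1], d[0])))


def decompose_saccade(
    fix_a,
    fix_b,
    forward_axis: np.ndarray = DEFAULT_FORWARD_AXIS,
    head_minimal_deg: float = 1.0,
) -> AmplitudeDecomposition:
    """Decompose the gaze shift from ``fix_a`` to ``fix_b``.

    Both arguments need ``mean_eye_in_head``, ``mean_head_orientation``
    (scalar-last quaternion) attributes, i.e. per-fixation summaries.
    ``head_minimal_deg`` is the threshold under which a shift counts as
    carried out with (essentially) no head rotation.
    """
    e_a = normalize(np.asarray(fix_a.mean_eye_in_head, dtype=float))
    e_b = normalize(np.asarray(fix_b.mean_eye_in_head, dtype=float))
    r_a = _as_rotation(fix_a.mean_head_orientation)
    r_b = _as_rotation(fix_b.mean_head_orientation)

    eye_amp = float(angle_between_deg(e_a, e_b))
    f = normalize(forward_axis)
    head_amp = float(angle_between_deg(r_a.apply(f), r_b.apply(f)))
    world_amp = float(angle_between_deg(r_a.apply(e_a), r_b.apply(e_b)))
    return AmplitudeDecomposition(
        eye_in_head_amp=eye_amp,
        head_amp=head_amp,
        eye_in_world_amp=world_amp,
        eye_contribution=eye_contribution(eye_amp, head_amp),
        head_dominant=head_amp > eye_amp,
        cancels=cancellation(fix_a, fix_b, forward_axis=forward_axis),
        head_minimal=head_amp < head_minimal_deg,
    )


def cancellation(fix_a, fix_b, forward_axis: np.ndarray = DEFAULT_FORWARD_AXIS) -> bool:
    """Do eye and head move in opposing horizontal directions?

    Operationalized as opposite signs of the azimuthal displacement of the
    eye-in-head direction (head frame) and of the head forward axis (world
    frame).  Zero eye displacement is never a cancellation.
    """
    e_a = normalize(np.asarray(fix_a.mean_eye_in_head, dtype=float))
    e_b = normalize(np.asarray(fix_b.mean_eye_in_head, dtype=float))
    f = normalize(forward_axis)
    d_eye = wrap_deg(azimuth_deg(e_b) - azimuth_deg(e_a))
    h_a = _as_rotation(fix_a.mean_head_orientation).apply(f)
    h_b = _as_rotation(fix_b.mean_head_orientation).apply(f)
    d_head = wrap_deg(azimuth_deg(h_b) - azimuth_deg(h_a))
    return bool(d_eye * d_head < 0.0)


_GIMBAL_TOL = 1e-7


def head_euler(orientation) -> EulerAngles:
    """Intrinsic yaw -> pitch -> roll decomposition of a head quaternion.

    The rotation is factored as Rz(yaw) Ry(-pitch) Rx(roll) acting on the
    canonical pose (forward +x, up +z), which makes pitch positive when
    the head tips up and roll positive toward the wearer's right.
    """
    r = _as_rotation(orientation)
    yaw, ry, roll = r.as_euler("ZYX", degrees=True)
    pitch = -ry
    gimbal = bool(abs(abs(pitch) - 90.0) < 1e-6)
    if gimbal:
        # scipy already resolves the degeneracy with the third angle := 0
        roll = 0.0
    return EulerAngles(roll=float(roll), pitch=float(pitch), yaw=float(yaw), gimbal=gimbal)


def euler_to_quat(roll: float, pitch: float, yaw: float) -> np.ndarray:
    """Inverse of :func:`head_euler`; returns a scalar-last quaternion."""
    r = Rotation.from_euler("ZYX", [yaw, -pitch, roll], degrees=True)
    return r.as_quat()


def standing_height(head_z: np.ndarray, k: float = 3.0) -> float:
    """Standing head height: maximum elevation after k-SD spike removal.

    Mocap spikes are removed with the same single-pass outlier rule used
    for angles; the maximum of the remaining samples estimates the
    upright head height.
    """
    z = np.asarray(head_z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("no head elevation samples")
    return float(z[sd_outlier_mask(z, k)].max())


def relative_elevation(fixation_head_z: float | np.ndarray, standing: float):
    """Head elevation relative to standing height (<= 0 except for noise)."""
    return np.asarray(fixation_head_z, dtype=float) - standing
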