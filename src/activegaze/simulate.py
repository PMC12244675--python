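"""Scripted synthetic searcher.

Generates ground-truthed recordings of a searcher walking, turning and
fixating in a layout, emulating the 50 Hz eye tracker and the 120 Hz
motion-capture head stream.  The simulator is a measurement-chain test
harness, not a behaviour model: its value is that every downstream stage
(merge, detect, classify, metrics, models) can be checked against the
script that produced the data.

Behavioural defaults are calibrated to the regime of real searchers in
this arena (target-present trials around 50 fixations / 9 m / 25 s,
target-absent roughly double), but they are generator settings, not
assertions.

Timeline construction guarantees exact recoverability at zero noise:

* gaze-channel event boundaries lie on the 50 Hz sample grid (fixation
  durations are multiples of 20 ms, scripted saccades last 40 ms and move
  at least ~2.5 deg, far above the 30 deg/s detection threshold);
* head-pose corner keyframes (walk waypoints, head-rotation windows inside
  saccades) lie on the 120 Hz grid, so linear/spherical resampling at gaze
  timestamps is exact;
* walk events begin and end on the common 0.1 s grid.

Head orientation is held constant during fixations and walks and rotates
only inside saccade windows, with a configurable eye/head split: each
gaze shift turns the head toward the new target by a randomly drawn gain
and the eyes take up the (possibly counter-rotating) residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation, Slerp

from ._util import angle_between_deg, normalize
from .geometry import euler_to_quat
from .intersect import classify_ray, first_hit
from .recording import RawRecording
from .scene import Box, Layout, ObjectPlacement, ORIENTATIONS

__all__ = [
    "TrialCondition",
    "ScriptEvent",
    "GroundTruth",
    "BehaviorParams",
    "SET_SIZES",
    "generate_design",
    "generate_trial",
    "simulate_subject",
    "inject_dropouts",
    "add_sensor_noise",
]

SET_SIZES = (30, 40, 50, 60)

GAZE_DT = 0.02      # 50 Hz eye tracker
HEAD_DT = 1.0 / 120.0  # 120 Hz mocap
WALK_GRID = 0.1     # common multiple of both sample periods
SACCADE_DUR = 0.04  # two gaze sample intervals


@dataclass(frozen=True)
class TrialCondition:
    """The manipulated variables of one trial."""

    target_present: bool
    set_size: int
    visible_from_start: bool | None = None
    target_orientation: str | None = None
    target_surface: str | None = None

    def __post_init__(self) -> None:
        if self.set_size not in SET_SIZES:
            raise ValueError(f"set_size must be one of {SET_SIZES}")
        if not self.target_present and self.visible_from_start is not None:
            raise ValueError("visible_from_start is defined only for present trials")


@dataclass(frozen=True)
class ScriptEvent:
    """One scripted behavioural event (semantic level)."""

    kind: str          # fixate | saccade | walk
    t_start: float
    t_end: float
    label: str | None = None          # scripted look-at label (fixate)
    aim: tuple | None = None          # world aim point (fixate)
    path: tuple | None = None         # waypoint tuple (walk)
    is_target: bool = False


@dataclass
class GroundTruth:
    """The pre-noise script against which recovery is measured."""

    events: list[ScriptEvent]
    true_fixation_count: int
    true_lookat_sequence: list[str]
    true_distance: float
    true_amplitudes: list[tuple[float, float, float]]  # (eye, head, world) deg
    condition: TrialCondition
    response: str
    duration: float
    target_placement: ObjectPlacement | None = None
    fixation_is_target: list[bool] = field(default_factory=list)
    fixation_windows: list[tuple[float, float]] = field(default_factory=list)


@dataclass(frozen=True)
class BehaviorParams:
    """Tunable searcher behaviour (durations s, lengths m, angles deg)."""

    eye_height: float = 1.62
    walk_speed: float = 0.62
    fixation_mean: float = 0.21
    fixation_sd: float = 0.09
    fixation_min: float = 0.08
    target_fixation_mean: float = 0.45
    per_visit_fixations: float = 4.6     # scaled by set_size / 45
    walk_fix_duration: float = 0.40
    p_box_glance: float = 0.55           # walk scans that land on furniture
    glance_head_gain: float = 0.35
    n_target_fixations: int = 3
    n_initial_scan: int = 2
    absent_extra_revisits: float = 3.0
    min_saccade_amp: float = 2.5
    head_gain_mean: float = 1.0
    head_gain_sd: float = 0.35
    p_false_negative: float = 0.125
    p_false_positive: float = 0.058
    crouch_offset: float = 0.55          # head sits ~this far above the viewed surface
    min_head_z: float = 1.15


# ---------------------------------------------------------------------------
# design enumeration

def generate_design(
    n_layouts: int = 4,
    n_versions: int = 6,
    subjects_per_cell: int = 3,
    trials_per_subject: int = 12,
    seed: int = 0,
    surfaces: tuple[str, ...] = ("T1", "T2", "T3", "C1", "C2", "C3", "C4", "C5", "C6"),
) -> pd.DataFrame:
    """Enumerate the counterbalanced between-subjects design.

    One row per (subject, trial).  Target presence is fully counterbalanced
    within each subject (hence ``trials_per_subject`` must be even); set
    sizes and start-visibility are evenly distributed, with cell
    assignments rotated across subjects.
    """
    if min(n_layouts, n_versions, subjects_per_cell, trials_per_subject) < 1:
        raise ValueError("all design counts must be >= 1")
    if trials_per_subject % 2:
        raise ValueError("trials_per_subject must be even to counterbalance presence")
    rows = []
    subject = 0
    for layout in range(1, n_layouts + 1):
        for version in range(1, n_versions + 1):
            for _ in range(subjects_per_cell):
                subject += 1
                rng = np.random.default_rng([seed, subject])
                half = trials_per_subject // 2
                presence = np.array([True] * half + [False] * half)
                rng.shuffle(presence)
                sizes = [SET_SIZES[(subject + i) % len(SET_SIZES)] for i in range(trials_per_subject)]
                rng.shuffle(sizes)
                # alternate visibility across this subject's present trials
                vis_cycle = [(subject + i) % 2 == 0 for i in range(half)]
                oris = [ORIENTATIONS[(subject + i) % len(ORIENTATIONS)] for i in range(half)]
                surfs = [surfaces[(subject * 3 + i) % len(surfaces)] for i in range(half)]
                p = 0
                for trial in range(1, trials_per_subject + 1):
                    present = bool(presence[trial - 1])
                    rows.append(
                        {
                            "subject": subject,
                            "layout": layout,
                            "version": version,
                            "trial": trial,
                            "target_present": present,
                            "set_size": sizes[trial - 1],
                            "visible_from_start": vis_cycle[p] if present else None,
                            "target_orientation": oris[p] if present else None,
                            "target_surface": surfs[p] if present else None,
                        }
                    )
                    if present:
                        p += 1
    return pd.DataFrame(rows)


def condition_from_row(row) -> TrialCondition:
    present = bool(row["target_present"])
    return TrialCondition(
        target_present=present,
        set_size=int(row["set_size"]),
        visible_from_start=bool(row["visible_from_start"]) if present else None,
        target_orientation=row["target_orientation"] if present else None,
        target_surface=row["target_surface"] if present else None,
    )


# ---------------------------------------------------------------------------
# grid helpers

def _snap_up(t: float, grid: float) -> float:
    return math.ceil(t / grid - 1e-9) * grid


def _quantize_duration(d: float, grid: float = GAZE_DT, minimum: float = 0.08) -> float:
    return max(minimum, _snap_up(d, grid))


# ---------------------------------------------------------------------------
# viewpoints and routing

def _viewing_pose(layout: Layout, box: Box, eye_z: float):
    """A standing position and aim point from which the gaze ray's first
    hit is this box.  Prefers the open face of cages."""
    candidates = []
    if box.is_cage:
        order = sorted(
            ("+x", "-x", "+y", "-y"),
            key=lambda f: 0 if box.faces[f].value == "open" else 1,
        )
        for f in order:
            candidates.append((f, box.face_center(f)))
    else:
        for f in ("+x", "-x", "+y", "-y"):
            # aim at the near strip of the table top, trying several spots
            # along the edge (cages on the table may shadow the center)
            c = box.face_center(f)
            edge_axis = 1 if f[1] == "x" else 0
            half = box.dims[edge_axis] / 2.0
            for frac in (0.0, -0.3, 0.3, -0.45, 0.45):
                aim = c + box.face_normal(f) * (-0.18)
                aim[edge_axis] += frac * 2.0 * half * 0.5
                aim[2] = box.top
                candidates.append((f, aim))
    bx, by = layout.arena_bounds
    for dist in (1.0, 1.2, 0.8, 1.5):
        for f, aim in candidates:
            n = box.face_normal(f)
            vp = box.face_center(f)[:2] + n[:2] * dist
            if not (0.2 <= vp[0] <= bx - 0.2 and 0.2 <= vp[1] <= by - 0.2):
                continue
            if any(
                t.lo[0] - 0.1 <= vp[0] <= t.hi[0] + 0.1
                and t.lo[1] - 0.1 <= vp[1] <= t.hi[1] + 0.1
                for t in layout.tables
            ):
                continue
            origin = np.array([vp[0], vp[1], eye_z])
            hit = first_hit(origin, normalize(aim - origin), layout)
            if hit is not None and hit.box_id == box.id:
                return np.array([vp[0], vp[1]]), aim, f
    raise ValueError(f"no admissible viewpoint for box {box.id}")


def _route_around_tables(layout: Layout, p0: np.ndarray, p1: np.ndarray, depth: int = 3):
    """Waypoints from p0 to p1 detouring around table footprints (2D)."""
    if depth == 0:
        return [p1]
    for t in layout.tables:
        lo, hi = t.lo[:2] - 0.25, t.hi[:2] + 0.25
        if _segment_crosses_rect(p0, p1, lo, hi):
            corners = np.array(
                [[lo[0], lo[1]], [lo[0], hi[1]], [hi[0], lo[1]], [hi[0], hi[1]]]
            )
            bx, by = layout.arena_bounds
            ok = corners[
                (corners[:, 0] > 0.2) & (corners[:, 0] < bx - 0.2)
                & (corners[:, 1] > 0.2) & (corners[:, 1] < by - 0.2)
            ]
            if len(ok) == 0:
                break
            detour = ok[np.argmin(np.linalg.norm(ok - p0, axis=1) + np.linalg.norm(ok - p1, axis=1))]
            return (
                _route_around_tables(layout, p0, detour, depth - 1)
                + _route_around_tables(layout, detour, p1, depth - 1)
            )
    return [p1]


def _segment_crosses_rect(p0, p1, lo, hi) -> bool:
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for a in range(2):
        if abs(d[a]) < 1e-12:
            if not (lo[a] <= p0[a] <= hi[a]):
                return False
            continue
        ta, tb = (lo[a] - p0[a]) / d[a], (hi[a] - p0[a]) / d[a]
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 > t1:
            return False
    return t1 - t0 > 1e-9


# ---------------------------------------------------------------------------
# script assembly

class _ScriptBuilder:
    """Accumulates keyframed channels on the exactness-preserving grids."""

    def __init__(self, layout: Layout, start_xy: np.ndarray, eye_z: float):
        self.layout = layout
        self.t = 0.0
        self.pos = np.array([start_xy[0], start_xy[1], eye_z])
        self.quat = euler_to_quat(0.0, 0.0, -90.0)  # facing the arena (-y-ish)
        self.eye = np.array([1.0, 0.0, 0.0])
        self.pos_keys: list[tuple[float, np.ndarray]] = [(0.0, self.pos.copy())]
        self.ori_keys: list[tuple[float, np.ndarray]] = [(0.0, self.quat.copy())]
        self.segments: list[tuple[str, float, float, np.ndarray, np.ndarray]] = []
        self.events: list[ScriptEvent] = []
        self.fix_records: list[dict] = []
        self.started = False
        self.glance_targets: list[np.ndarray] = []   # world points glanced at mid-walk

    # -- channels ----------------------------------------------------------
    def _saccade_to(self, new_quat: np.ndarray, new_eye: np.ndarray):
        s0 = self.t
        s1 = s0 + SACCADE_DUR
        self.segments.append(("sacc", s0, s1, self.eye.copy(), new_eye.copy()))
        if not np.allclose(new_quat, self.quat):
            h0 = _snap_up(s0, HEAD_DT)
            h1 = math.floor(s1 / HEAD_DT + 1e-9) * HEAD_DT
            if h1 <= h0 + 1e-12:
                h1 = h0 + HEAD_DT
            self.ori_keys.append((h0, self.quat.copy()))
            self.ori_keys.append((h1, new_quat.copy()))
        self.events.append(ScriptEvent("saccade", s0, s1))
        self.quat = new_quat
        self.eye = new_eye
        self.t = s1

    def fixate(self, aim: np.ndarray, duration: float, head_gain: float,
               is_target: bool = False, min_amp: float = 0.0) -> bool:
        """Shift gaze to a world point and hold it.  Returns False if the
        required eye-in-head shift is below ``min_amp`` (caller may re-aim).
        """
        direction = normalize(aim - self.pos)
        new_quat = self._head_toward(direction, head_gain)
        new_eye = Rotation.from_quat(new_quat).inv().apply(direction)
        if self.started and min_amp > 0.0 and angle_between_deg(self.eye, new_eye) < min_amp:
            return False
        if self.started:
            self._saccade_to(new_quat, new_eye)
        else:
            self.quat, self.eye = new_quat, new_eye
            self.ori_keys[-1] = (0.0, new_quat.copy())
            self.started = True
        self._hold(duration, aim=aim, is_target=is_target)
        return True

    def _hold(self, duration: float, aim=None, is_target=False):
        t0, t1 = self.t, self.t + duration
        self.segments.append(("fix", t0, t1, self.eye.copy(), self.eye.copy()))
        self.events.append(
            ScriptEvent("fixate", t0, t1,
                        aim=tuple(aim) if aim is not None else None,
                        is_target=is_target)
        )
        # the look-at label is evaluated in _emit at the fixation's mean
        # head position (the head may translate under a held gaze)
        self.fix_records.append(
            {
                "t0": t0, "t1": t1,
                "eye": self.eye.copy(), "quat": self.quat.copy(),
                "is_target": is_target,
            }
        )
        self.t = t1

    def _head_toward(self, direction: np.ndarray, gain: float) -> np.ndarray:
        """Rotate the head's forward axis toward ``direction`` by ``gain``
        of the separating angle (yaw and pitch only, no roll)."""
        fwd = Rotation.from_quat(self.quat).apply([1.0, 0.0, 0.0])
        ang = math.radians(angle_between_deg(fwd, direction))
        if ang < 1e-9:
            return self.quat.copy()
        frac = np.clip(gain, 0.0, 180.0 / math.degrees(ang) if ang else 1.0)
        axis = np.cross(fwd, direction)
        nrm = np.linalg.norm(axis)
        if nrm < 1e-12:
            new_fwd = direction
        else:
            rot = Rotation.from_rotvec(axis / nrm * ang * frac)
            new_fwd = rot.apply(fwd)
        yaw = math.degrees(math.atan2(new_fwd[1], new_fwd[0]))
        pitch = math.degrees(math.asin(np.clip(new_fwd[2], -1.0, 1.0)))
        return euler_to_quat(0.0, pitch, yaw)

    def walk(self, dest_xy: np.ndarray, dest_z: float, speed: float,
             rng: np.random.Generator, walk_fix: float,
             p_glance: float = 0.55, glance_gain: float = 0.35,
             min_amp: float = 2.5):
        """Walk to a new standing point, scanning with short gaze holds.

        Scanning gaze alternates between jittered ahead-of-travel holds
        and glances at furniture; the head yaw-jitters a few degrees at
        each scan shift.  Proposed shifts below the minimum registrable
        amplitude are absorbed into the running hold instead of emitting
        an undetectable saccade.
        """
        waypoints = [self.pos[:2].copy()] + _route_around_tables(
            self.layout, self.pos[:2], np.asarray(dest_xy, dtype=float)
        )
        legs = np.diff(np.asarray(waypoints), axis=0)
        lens = np.linalg.norm(legs, axis=1)
        total = float(lens.sum())
        if total < 1e-6:
            return
        # face the direction of travel, gaze jittered around straight ahead
        travel = np.array([legs[0][0], legs[0][1], 0.0])
        walk_quat = self._head_toward(normalize(travel), 1.0)
        first_eye = _dir_from_angles(rng.uniform(4.0, 12.0), rng.uniform(0.0, 8.0))
        self._saccade_to(walk_quat, first_eye)

        w0 = _snap_up(self.t, WALK_GRID)                 # motion start
        dur = max(WALK_GRID, _snap_up(total / speed, WALK_GRID))
        w1 = w0 + dur
        # position keyframes: stationary until w0, corners on the 120 Hz grid
        z0, z1 = self.pos[2], dest_z
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        self.pos_keys.append((w0, self.pos.copy()))
        times = w0 + cum / total * dur
        times = np.round(times / HEAD_DT) * HEAD_DT
        times[0], times[-1] = w0, w1
        key_pts = [self.pos.copy()]
        for i in range(1, len(waypoints)):
            ti = min(max(times[i], times[i - 1] + HEAD_DT), w1)
            frac = cum[i] / total
            p = np.array([waypoints[i][0], waypoints[i][1], z0 + (z1 - z0) * frac])
            self.pos_keys.append((ti, p))
            times[i] = ti
            key_pts.append(p)
        key_pts = np.asarray(key_pts)

        def pos_at(t):
            return np.array([np.interp(t, times, key_pts[:, a]) for a in range(3)])

        self.events.append(ScriptEvent("walk", w0, w1, path=tuple(map(tuple, waypoints))))
        # scanning holds fill [saccade end, w1]; shift boundaries stay on
        # the gaze grid, so detection recovers every hold exactly
        holds = [h for h in _chunk_holds(w1 - self.t, walk_fix) if h is not None]
        self._hold(holds[0])
        sign = -1.0
        for hold in holds[1:]:
            proposal = None
            for _try in range(4):
                new_quat, new_eye = self._propose_scan(rng, pos_at(self.t), sign,
                                                       p_glance, glance_gain)
                if angle_between_deg(new_eye, self.eye) >= min_amp:
                    proposal = (new_quat, new_eye)
                    break
            sign = -sign
            if proposal is None:
                self._extend_hold(hold + SACCADE_DUR)
            else:
                self._saccade_to(*proposal)
                self._hold(hold)
        self.pos = np.array([dest_xy[0], dest_xy[1], dest_z])
        self.t = w1

    def _propose_scan(self, rng, here, sign, p_glance, glance_gain):
        """Next scanning gaze: a furniture glance or an ahead-of-travel
        jitter, with a small head yaw adjustment either way."""
        fwd = Rotation.from_quat(self.quat).apply([1.0, 0.0, 0.0])
        if self.glance_targets and rng.random() < p_glance:
            aim = self.glance_targets[int(rng.integers(len(self.glance_targets)))]
            d = aim - here
            n = np.linalg.norm(d)
            if n > 0.3:
                d = d / n
                if angle_between_deg(fwd, d) < 75.0:
                    new_quat = self._head_toward(d, glance_gain)
                    new_eye = Rotation.from_quat(new_quat).inv().apply(d)
                    return new_quat, new_eye
        # ahead-of-travel jitter with a small head yaw delta
        delta = sign * rng.uniform(0.0, 6.0)
        yaw = math.degrees(math.atan2(fwd[1], fwd[0])) + delta
        new_quat = euler_to_quat(0.0, 0.0, yaw)
        new_eye = _dir_from_angles(sign * rng.uniform(4.0, 12.0), rng.uniform(0.0, 8.0))
        return new_quat, new_eye

    def _extend_hold(self, dt: float):
        """Lengthen the current hold (an undetectably small shift was
        absorbed rather than scripted)."""
        kind, t0, t1, e0, e1 = self.segments[-1]
        assert kind == "fix"
        self.segments[-1] = (kind, t0, t1 + dt, e0, e1)
        self.fix_records[-1]["t1"] += dt
        ev = self.events[-1]
        self.events[-1] = replace(ev, t_end=ev.t_end + dt)
        self.t += dt


def _dir_from_angles(azimuth_deg_: float, elevation_deg: float) -> np.ndarray:
    az, el = math.radians(azimuth_deg_), math.radians(elevation_deg)
    return np.array([math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)])


def _chunk_holds(remaining: float, walk_fix: float) -> list[float | None]:
    """Split a walk's gaze time into holds separated by saccades (None).

    All holds are multiples of the gaze period and at least 80 ms so the
    detector keeps every one of them.
    """
    remaining = round(remaining / GAZE_DT) * GAZE_DT
    n = max(1, int(round(remaining / (walk_fix + SACCADE_DUR))))
    while n > 1:
        hold_total = remaining - (n - 1) * SACCADE_DUR
        base = math.floor(hold_total / n / GAZE_DT + 1e-9) * GAZE_DT
        if base >= 0.08:
            break
        n -= 1
    hold_total = remaining - (n - 1) * SACCADE_DUR
    base = math.floor(hold_total / n / GAZE_DT + 1e-9) * GAZE_DT
    out: list[float | None] = []
    for i in range(n):
        out.append(hold_total - base * (n - 1) if i == n - 1 else base)
        if i < n - 1:
            out.append(None)
    return out


# ---------------------------------------------------------------------------
# trial generation

def _target_placement(layout: Layout, condition: TrialCondition) -> ObjectPlacement:
    box = layout.box(condition.target_surface)
    stacked = layout.stacked_pairs()
    lower_ids = {a.id for a, _ in stacked}
    if box.is_table:
        pos = box.center.copy()
        pos[2] = box.top + 0.02
    elif box.id in lower_ids:
        pos = box.center.copy()  # inside the cage, on its floor
        pos[2] = box.lo[2] + 0.02
    else:
        pos = box.center.copy()  # on top of the cage
        pos[2] = box.top + 0.02
    return ObjectPlacement(
        object_id="target",
        position=pos,
        surface=box.id,
        orientation=condition.target_orientation or "upright",
        extent=0.08,
        is_target=True,
    )


def _aim_on_box(box: Box, face: str, aim_center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Jittered aim point on the viewed face, keeping a safety margin."""
    aim = np.asarray(aim_center, dtype=float).copy()
    axes = [a for a in range(3) if abs(box.face_normal(face)[a]) < 0.5]
    for a in axes:
        half = box.dims[a] / 2.0
        lo = max(box.lo[a] + 0.06, aim_center[a] - 0.3 * half)
        hi = min(box.hi[a] - 0.06, aim_center[a] + 0.3 * half)
        if hi > lo:
            aim[a] = rng.uniform(lo, hi)
    return aim


def _draw_fix_duration(rng, mean, sd, minimum) -> float:
    shape = (mean / sd) ** 2 if sd > 0 else 1e6
    d = rng.gamma(shape, mean / shape) if sd > 0 else mean
    return _quantize_duration(d, GAZE_DT, minimum)


def generate_trial(
    layout: Layout,
    condition: TrialCondition,
    params: BehaviorParams = BehaviorParams(),
    seed: int = 0,
) -> tuple[RawRecording, GroundTruth]:
    """Simulate one trial; returns the clean recording and its script.

    Identical (layout, condition, params, seed) give identical output.
    Noise and dropouts are separate, explicit operations
    (:func:`add_sensor_noise`, :func:`inject_dropouts`).
    """
    if condition.target_present and condition.target_surface not in layout.box_ids:
        raise ValueError(f"target surface {condition.target_surface!r} not in layout")
    rng = np.random.default_rng([seed])
    eye_z = params.eye_height
    poses = {b.id: _viewing_pose(layout, b, eye_z) for b in layout.boxes}

    order = list(rng.permutation(layout.box_ids))
    response, visits, target_placement = _plan_route(condition, order, params, rng)

    builder = _ScriptBuilder(layout, layout.start_location[:2], eye_z)
    builder.glance_targets = [np.asarray(aim, dtype=float) for (_vp, aim, _f) in poses.values()]
    per_visit = params.per_visit_fixations * condition.set_size / 45.0

    # initial scan from the start corner
    for k in range(params.n_initial_scan):
        vp, aim, face = poses[visits[min(k, len(visits) - 1)]]
        dur = _draw_fix_duration(rng, params.fixation_mean, params.fixation_sd, params.fixation_min)
        builder.fixate(np.asarray(aim, dtype=float), dur,
                       head_gain=_draw_gain(rng, params),
                       min_amp=params.min_saccade_amp if k else 0.0)

    placement = _target_placement(layout, condition) if condition.target_present else None
    for vi, box_id in enumerate(visits):
        box = layout.box(box_id)
        vp, aim_center, face = poses[box_id]
        crouch_z = float(np.clip(box.top + params.crouch_offset - 0.25,
                                 params.min_head_z, eye_z))
        builder.walk(vp, crouch_z, params.walk_speed, rng, params.walk_fix_duration,
                     p_glance=params.p_box_glance, glance_gain=params.glance_head_gain,
                     min_amp=params.min_saccade_amp)
        n_fix = max(1, int(rng.poisson(per_visit)))
        for _ in range(n_fix):
            dur = _draw_fix_duration(rng, params.fixation_mean, params.fixation_sd, params.fixation_min)
            for _try in range(6):
                aim = _aim_on_box(box, face, aim_center, rng)
                if builder.fixate(aim, dur, head_gain=_draw_gain(rng, params),
                                  min_amp=params.min_saccade_amp):
                    break
        if (
            condition.target_present
            and box_id == condition.target_surface
            and response == "present"
        ):
            for _ in range(params.n_target_fixations):
                dur = _draw_fix_duration(
                    rng, params.target_fixation_mean, params.fixation_sd, params.fixation_min
                )
                for _try in range(6):
                    # scatter confirmation aims around the target widely
                    # enough that consecutive shifts register as saccades
                    aim = placement.position + rng.normal(0.0, [0.06, 0.06, 0.03])
                    if builder.fixate(aim, dur, head_gain=_draw_gain(rng, params),
                                      is_target=True, min_amp=params.min_saccade_amp):
                        break

    return _emit(builder, layout, condition, response, placement)


def _draw_gain(rng, params: BehaviorParams) -> float:
    return float(np.clip(rng.normal(params.head_gain_mean, params.head_gain_sd), 0.2, 1.8))


def _plan_route(condition, order, params, rng):
    """Visit order, response and error bookkeeping for one trial."""
    if condition.target_present:
        tgt = condition.target_surface
        order = [b for b in order if b != tgt]
        if condition.visible_from_start:
            idx = int(rng.integers(0, 2))
        else:
            idx = int(rng.integers(len(order) // 2, len(order) + 1))
        order.insert(idx, tgt)
        if rng.random() < params.p_false_negative:
            response = "absent"          # searcher misses; walks the full route
            visits = order
        else:
            response = "present"
            visits = order[: order.index(tgt) + 1]
    else:
        extra = int(rng.poisson(params.absent_extra_revisits))
        revisit = [order[int(rng.integers(len(order)))] for _ in range(extra)]
        revisit = [b for i, b in enumerate(revisit)
                   if (revisit[i - 1] if i else order[-1]) != b]
        visits = order + revisit
        response = "present" if rng.random() < params.p_false_positive else "absent"
    return response, visits, None


def _emit(builder: _ScriptBuilder, layout, condition, response, placement):
    """Sample the keyframed script into 50/120 Hz streams + ground truth."""
    t_end = builder.t
    n_gaze = int(round(t_end / GAZE_DT)) + 1
    gt_t = np.arange(n_gaze) * GAZE_DT
    eye = np.empty((n_gaze, 3))
    gaze_pt = np.full((n_gaze, 3), np.nan)
    for kind, t0, t1, e0, e1 in builder.segments:
        i0 = int(math.ceil(t0 / GAZE_DT - 1e-9))
        i1 = min(n_gaze - 1, int(math.floor(t1 / GAZE_DT + 1e-9)))
        if i1 < i0:
            continue
        idx = np.arange(i0, i1 + 1)
        if kind == "fix" or np.allclose(e0, e1):
            eye[idx] = e0
        else:
            u = (gt_t[idx] - t0) / (t1 - t0)
            ang = math.radians(angle_between_deg(e0, e1))
            if ang < 1e-12:
                eye[idx] = e0
            else:
                axis = np.cross(e0, e1)
                axis = axis / np.linalg.norm(axis)
                rots = Rotation.from_rotvec(np.outer(u * ang, axis))
                eye[idx] = rots.apply(e0)
    gaze = pd.DataFrame(
        {
            "t": gt_t,
            "ex": eye[:, 0], "ey": eye[:, 1], "ez": eye[:, 2],
            "gx": gaze_pt[:, 0], "gy": gaze_pt[:, 1], "gz": gaze_pt[:, 2],
            "valid_left": True, "valid_right": True,
        }
    )

    # one extra mocap sample so the head timeline covers every gaze sample
    n_head = int(math.ceil(t_end / HEAD_DT - 1e-9)) + 2
    ht = np.arange(n_head) * HEAD_DT
    pos_keys = _dedupe_keys(builder.pos_keys, t_end)
    kt = np.array([k[0] for k in pos_keys])
    kp = np.array([k[1] for k in pos_keys])
    hp = np.column_stack([np.interp(ht, kt, kp[:, a]) for a in range(3)])
    ori_keys = _dedupe_keys(builder.ori_keys, t_end)
    ot = np.array([k[0] for k in ori_keys])
    oq = np.array([k[1] for k in ori_keys])
    if len(ot) > 1:
        hq = Slerp(ot, Rotation.from_quat(oq))(np.clip(ht, ot[0], ot[-1])).as_quat()
    else:
        hq = np.repeat(oq, n_head, axis=0)
    head = pd.DataFrame(
        {
            "t": ht,
            "hx": hp[:, 0], "hy": hp[:, 1], "hz": hp[:, 2],
            "qx": hq[:, 0], "qy": hq[:, 1], "qz": hq[:, 2], "qw": hq[:, 3],
        }
    )
    markers = pd.DataFrame(
        [{"trial": 1, "t_start": 0.0, "t_end": t_end, "response": response}]
    )
    rec = RawRecording(gaze=gaze, head=head, markers=markers,
                      meta={"layout": layout.id})

    # ground truth evaluated on the same grids the pipeline will see
    true_pos = np.column_stack([np.interp(gt_t, kt, kp[:, a]) for a in range(3)])
    true_distance = float(np.linalg.norm(np.diff(true_pos, axis=0), axis=1).sum())
    recs = builder.fix_records
    for r in recs:
        i0 = int(math.ceil(r["t0"] / GAZE_DT - 1e-9))
        i1 = min(n_gaze - 1, int(math.floor(r["t1"] / GAZE_DT + 1e-9)))
        mean_pos = true_pos[i0 : i1 + 1].mean(axis=0)
        world_dir = Rotation.from_quat(r["quat"]).apply(r["eye"])
        r["label"] = classify_ray(mean_pos, world_dir, layout)
        r["mean_pos"] = mean_pos
    # mirror the evaluated labels back into the semantic event list
    rec_iter = iter(recs)
    builder.events = [
        replace(e, label=next(rec_iter)["label"]) if e.kind == "fixate" else e
        for e in builder.events
    ]
    amplitudes = []
    for a, b in zip(recs[:-1], recs[1:]):
        ra, rb = Rotation.from_quat(a["quat"]), Rotation.from_quat(b["quat"])
        amplitudes.append(
            (
                float(angle_between_deg(a["eye"], b["eye"])),
                float(angle_between_deg(ra.apply([1, 0, 0]), rb.apply([1, 0, 0]))),
                float(angle_between_deg(ra.apply(a["eye"]), rb.apply(b["eye"]))),
            )
        )
    gt = GroundTruth(
        events=builder.events,
        true_fixation_count=len(recs),
        true_lookat_sequence=[r["label"] for r in recs],
        true_distance=true_distance,
        true_amplitudes=amplitudes,
        condition=condition,
        response=response,
        duration=t_end,
        target_placement=placement,
        fixation_is_target=[r["is_target"] for r in recs],
        fixation_windows=[(r["t0"], r["t1"]) for r in recs],
    )
    return rec, gt


def _dedupe_keys(keys, t_end):
    keys = sorted(keys, key=lambda k: k[0])
    out = []
    for t, v in keys:
        if out and abs(t - out[-1][0]) < 1e-9:
            out[-1] = (t, v)
        else:
            out.append((t, v))
    if out[-1][0] < t_end:
        out.append((t_end, out[-1][1]))
    return out


# ---------------------------------------------------------------------------
# subject-level assembly

def simulate_subject(
    layout: Layout,
    conditions: list[TrialCondition],
    params: BehaviorParams = BehaviorParams(),
    seed: int = 0,
) -> tuple[RawRecording, list[GroundTruth]]:
    """Concatenate a subject's trials into one continuous recording.

    Trials are separated by ~1 s idle gaps (standing at the start corner);
    markers delimit the trial windows, so idle samples never reach the
    per-trial analyses.  Trial offsets stay on the common 0.1 s grid.
    """
    gaze_parts, head_parts, marker_rows, truths = [], [], [], []
    offset = 0.0
    for ti, cond in enumerate(conditions, start=1):
        rec, gt = generate_trial(layout, cond, params, seed=_trial_seed(seed, ti))
        g = rec.gaze.copy()
        h = rec.head.copy()
        g["t"] = g["t"] + offset
        h["t"] = h["t"] + offset
        gaze_parts.append(g)
        head_parts.append(h)
        marker_rows.append(
            {"trial": ti, "t_start": offset,
             "t_end": round((offset + gt.duration) / GAZE_DT) * GAZE_DT,
             "response": gt.response}
        )
        truths.append(gt)
        next_offset = _snap_up(offset + gt.duration + 1.0, WALK_GRID)
        gaze_parts.append(_idle_gaze(float(g["t"].iloc[-1]), next_offset))
        head_parts.append(_idle_head(float(h["t"].iloc[-1]), next_offset, layout, params))
        offset = next_offset
    gaze = pd.concat(gaze_parts, ignore_index=True)
    head = pd.concat(head_parts, ignore_index=True)
    # snap to the exact global sample grids so stream concatenation cannot
    # leave ulp-level duplicate timestamps
    gaze["t"] = np.round(gaze["t"] / GAZE_DT) * GAZE_DT
    head["t"] = np.round(head["t"] / HEAD_DT) * HEAD_DT
    gaze = gaze.drop_duplicates(subset="t").sort_values("t").reset_index(drop=True)
    head = head.drop_duplicates(subset="t").sort_values("t").reset_index(drop=True)
    markers = pd.DataFrame(marker_rows)
    return RawRecording(gaze=gaze, head=head, markers=markers,
                        meta={"layout": layout.id}), truths


def _trial_seed(seed: int, trial: int) -> int:
    return int(np.random.SeedSequence([seed, trial]).generate_state(1)[0] % (2**31 - 1))


def _idle_gaze(t0: float, t1: float) -> pd.DataFrame:
    """Fill [t0, t1) with stand-still gaze samples, starting one sample
    after the previous stream's last timestamp ``t0``."""
    n0 = int(round(t0 / GAZE_DT)) + 1
    n1 = int(math.ceil(t1 / GAZE_DT - 1e-9))
    t = np.arange(n0, n1) * GAZE_DT
    return pd.DataFrame(
        {"t": t, "ex": 1.0, "ey": 0.0, "ez": 0.0,
         "gx": np.nan, "gy": np.nan, "gz": np.nan,
         "valid_left": True, "valid_right": True}
    )


def _idle_head(t0: float, t1: float, layout: Layout, params: BehaviorParams) -> pd.DataFrame:
    n0 = int(round(t0 / HEAD_DT)) + 1
    n1 = int(math.ceil(t1 / HEAD_DT - 1e-9))
    t = np.arange(n0, n1) * HEAD_DT
    q = euler_to_quat(0.0, 0.0, -90.0)
    return pd.DataFrame(
        {"t": t,
         "hx": layout.start_location[0], "hy": layout.start_location[1],
         "hz": params.eye_height,
         "qx": q[0], "qy": q[1], "qz": q[2], "qw": q[3]}
    )


# ---------------------------------------------------------------------------
# degradation operators

def inject_dropouts(
    gaze: pd.DataFrame,
    dropout_rate: float,
    max_gap: float = 0.20,
    seed: int = 0,
    mean_gap: float = 0.06,
) -> pd.DataFrame:
    """Mark gaze samples invalid in runs (both-eye losses).

    A two-state Markov chain whose stationary invalid probability equals
    ``dropout_rate`` generates runs with mean duration ``mean_gap``,
    truncated at ``max_gap``.  Deterministic per seed; rate 0 returns an
    identical copy.
    """
    if not (0.0 <= dropout_rate < 1.0):
        raise ValueError("dropout_rate must be in [0, 1)")
    out = gaze.copy()
    if dropout_rate == 0.0 or len(gaze) == 0:
        return out
    dt = float(np.median(np.diff(gaze["t"].to_numpy()))) if len(gaze) > 1 else GAZE_DT
    mean_run = max(1, round(mean_gap / dt))
    cap = max(mean_run, round(max_gap / dt))
    q = 1.0 / mean_run                                  # exit probability
    p = dropout_rate * q / (1.0 - dropout_rate)         # entry probability
    rng = np.random.default_rng([seed])
    invalid = np.zeros(len(gaze), dtype=bool)
    state, run = False, 0
    u = rng.random(len(gaze))
    for i in range(len(gaze)):
        if state:
            run += 1
            if u[i] < q or run >= cap:
                state, run = False, 0
        else:
            if u[i] < p:
                state, run = True, 1
        invalid[i] = state
    out.loc[invalid, ["valid_left", "valid_right"]] = False
    return out


def add_sensor_noise(
    recording: RawRecording,
    gaze_sd: float = 1.29,
    head_pos_sd: float = 0.0002,
    seed: int = 0,
    rho: float = 0.985,
) -> RawRecording:
    """Perturb the recording with tracker-like measurement noise.

    Gaze directions receive an isotropic tangent-plane angular offset whose
    magnitude has mean ``gaze_sd`` degrees (the tracker's printed precision
    error while walking).  The offset evolves as an AR(1) process
    (``rho`` per sample), mimicking slippage-dominated error: the apparent
    gaze drifts around the true line of sight rather than flickering, so
    sample-to-sample velocities stay compatible with fixation detection.
    Head positions receive iid Gaussian noise of SD ``head_pos_sd`` meters
    per component.  Zero SDs return an identical copy.
    """
    if gaze_sd < 0 or head_pos_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    rng = np.random.default_rng([seed])
    gaze = recording.gaze.copy()
    head = recording.head.copy()
    if gaze_sd > 0 and len(gaze):
        e = gaze[["ex", "ey", "ez"]].to_numpy(dtype=float)
        n = len(e)
        sigma = math.radians(gaze_sd) / math.sqrt(math.pi / 2.0)
        eps = rng.normal(0.0, sigma, (n, 2))
        ab = np.empty((n, 2))
        ab[0] = eps[0]
        scale = math.sqrt(1.0 - rho**2)
        for i in range(1, n):
            ab[i] = rho * ab[i - 1] + scale * eps[i]
        # rotate each direction by angle r within its tangent plane
        up = np.where(np.abs(e[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
        u = np.cross(e, up)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(e, u)
        r = np.linalg.norm(ab, axis=1)
        phi = np.arctan2(ab[:, 1], ab[:, 0])
        tangent = u * np.cos(phi)[:, None] + v * np.sin(phi)[:, None]
        e_noisy = e * np.cos(r)[:, None] + tangent * np.sin(r)[:, None]
        gaze[["ex", "ey", "ez"]] = e_noisy
    if head_pos_sd > 0 and len(head):
        head[["hx", "hy", "hz"]] += rng.normal(0.0, head_pos_sd, (len(head), 3))
    return RawRecording(gaze=gaze, head=head, markers=recording.markers.copy(),
                        meta=dict(recording.meta))
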