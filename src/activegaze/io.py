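"""CSV/JSON round-tripping and the deposited-export adapter.

The simulator dialect stores one recording as three files in a directory:
``gaze.csv`` (50 Hz eye stream), ``head.csv`` (120 Hz rigid body) and
``markers.csv`` (trial windows), with the column layouts documented in
:mod:`activegaze.recording`.  Ground truth is JSON.

The deposited-export adapter maps externally exported column names (eye
tracker and mocap software dialects) onto the same RawRecording container.
Exports that provide a 3D gaze point instead of a gaze direction are
accepted; the direction is then back-computed from the merged head pose
with :func:`directions_from_points`.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .recording import GAZE_COLUMNS, HEAD_COLUMNS, MARKER_COLUMNS, RawRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_ground_truth",
    "fixations_frame",
    "saccades_frame",
    "DEPOSITED_GAZE_MAP",
    "DEPOSITED_HEAD_MAP",
    "load_deposited_export",
    "directions_from_points",
]


def save_recording(recording: RawRecording, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    recording.gaze.to_csv(d / "gaze.csv", index=False)
    recording.head.to_csv(d / "head.csv", index=False)
    recording.markers.to_csv(d / "markers.csv", index=False)
    if recording.meta:
        (d / "meta.json").write_text(json.dumps(recording.meta, default=str))


def load_recording(directory: str | Path) -> RawRecording:
    d = Path(directory)
    meta = {}
    if (d / "meta.json").exists():
        meta = json.loads((d / "meta.json").read_text())
    return RawRecording(
        gaze=pd.read_csv(d / "gaze.csv"),
        head=pd.read_csv(d / "head.csv"),
        markers=pd.read_csv(d / "markers.csv"),
        meta=meta,
    )


def save_ground_truth(truths, path: str | Path) -> None:
    """Serialize one trial's or a list of trials' ground truth to JSON."""
    if not isinstance(truths, list):
        truths = [truths]
    payload = []
    for gt in truths:
        d = asdict(gt)
        d["events"] = [asdict(e) if not isinstance(e, dict) else e for e in gt.events]
        payload.append(d)
    Path(path).write_text(json.dumps(payload, default=_json_default, indent=1))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    return str(o)


def fixations_frame(fixations) -> pd.DataFrame:
    rows = []
    for i, f in enumerate(fixations, start=1):
        rows.append(
            {
                "fixation": i,
                "t_start": f.t_start, "t_end": f.t_end, "duration": f.duration,
                "ex": f.mean_eye_in_head[0], "ey": f.mean_eye_in_head[1],
                "ez": f.mean_eye_in_head[2],
                "hx": f.mean_head_position[0], "hy": f.mean_head_position[1],
                "hz": f.mean_head_position[2],
                "qx": f.mean_head_orientation[0], "qy": f.mean_head_orientation[1],
                "qz": f.mean_head_orientation[2], "qw": f.mean_head_orientation[3],
                "label": f.lookat_label, "is_target": f.is_target_fixation,
            }
        )
    return pd.DataFrame(rows)


def saccades_frame(saccades) -> pd.DataFrame:
    rows = []
    for s in saccades:
        d = s.decomposition
        rows.append(
            {
                "from_fixation": s.from_fixation + 1,
                "to_fixation": s.to_fixation + 1,
                "t_start": s.t_start, "t_end": s.t_end,
                "eye_in_head_amp": d.eye_in_head_amp,
                "head_amp": d.head_amp,
                "eye_in_world_amp": d.eye_in_world_amp,
                "eye_contribution": d.eye_contribution,
                "head_dominant": d.head_dominant,
                "cancels": d.cancels,
                "head_minimal": d.head_minimal,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deposited-export adapter

#: default column mappings for the deposited experiment export.  Keys are
#: our canonical names, values the exported headers; override any of them
#: via the ``gaze_map`` / ``head_map`` arguments.
DEPOSITED_GAZE_MAP = {
    "t": "timestamp",
    "ex": "gaze_dir_x", "ey": "gaze_dir_y", "ez": "gaze_dir_z",
    "gx": "gaze_point_3d_x", "gy": "gaze_point_3d_y", "gz": "gaze_point_3d_z",
    "valid_left": "validity_left", "valid_right": "validity_right",
}

DEPOSITED_HEAD_MAP = {
    "t": "timestamp",
    "hx": "position_x", "hy": "position_y", "hz": "position_z",
    "qx": "rotation_x", "qy": "rotation_y", "qz": "rotation_z", "qw": "rotation_w",
}

DEPOSITED_MARKER_MAP = {
    "trial": "trial", "t_start": "trial_start", "t_end": "trial_end",
    "response": "response",
}


def load_deposited_export(
    gaze_path: str | Path,
    head_path: str | Path,
    markers_path: str | Path,
    gaze_map: dict | None = None,
    head_map: dict | None = None,
    marker_map: dict | None = None,
) -> RawRecording:
    """Read an externally exported recording into a RawRecording.

    The gaze export may carry the eye-in-head direction columns, the 3D
    gaze point columns, or both; with only gaze points, the direction
    channel is left missing and should be recovered after merging with
    :func:`directions_from_points`.
    """
    gmap = {**DEPOSITED_GAZE_MAP, **(gaze_map or {})}
    hmap = {**DEPOSITED_HEAD_MAP, **(head_map or {})}
    mmap = {**DEPOSITED_MARKER_MAP, **(marker_map or {})}
    graw = pd.read_csv(gaze_path)
    hraw = pd.read_csv(head_path)
    mraw = pd.read_csv(markers_path)

    gaze = pd.DataFrame()
    for ours, theirs in gmap.items():
        if theirs in graw.columns:
            gaze[ours] = graw[theirs]
    for col in GAZE_COLUMNS:
        if col not in gaze.columns:
            gaze[col] = np.nan if col not in ("valid_left", "valid_right") else True
    if gaze[["ex", "ey", "ez"]].isna().all().all() and gaze[["gx", "gy", "gz"]].isna().all().all():
        raise ValueError("export provides neither gaze directions nor gaze points")

    head = pd.DataFrame()
    for ours, theirs in hmap.items():
        if theirs not in hraw.columns:
            raise ValueError(f"head export missing column {theirs!r}")
        head[ours] = hraw[theirs]

    markers = pd.DataFrame({ours: mraw[theirs] for ours, theirs in mmap.items()})
    return RawRecording(gaze=gaze[GAZE_COLUMNS], head=head[HEAD_COLUMNS],
                        markers=markers[MARKER_COLUMNS])


def directions_from_points(merged: pd.DataFrame) -> pd.DataFrame:
    """Fill missing eye-in-head directions from world gaze points.

    For samples that carry a 3D gaze point but no direction, the direction
    is the head-frame unit vector from the interpolated head position to
    the gaze point.  Requires the merged frame to retain ``gx, gy, gz``.
    """
    out = merged.copy()
    have_dir = np.isfinite(out[["ex", "ey", "ez"]].to_numpy()).all(axis=1)
    have_pt = np.isfinite(out[["gx", "gy", "gz"]].to_numpy()).all(axis=1) if "gx" in out else np.zeros(len(out), bool)
    todo = ~have_dir & have_pt
    if not todo.any():
        return out
    g = out.loc[todo, ["gx", "gy", "gz"]].to_numpy(dtype=float)
    h = out.loc[todo, ["hx", "hy", "hz"]].to_numpy(dtype=float)
    q = out.loc[todo, ["qx", "qy", "qz", "qw"]].to_numpy(dtype=float)
    v = g - h
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    ok = norms[:, 0] > 1e-9
    v[ok] /= norms[ok]
    e = Rotation.from_quat(q).inv().apply(v)
    idx = out.index[todo]
    out.loc[idx, ["ex", "ey", "ez"]] = e
    out.loc[idx, "valid"] = out.loc[idx, "valid"] & ok if "valid" in out else ok
    return out
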