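"""Merging the gaze and head streams onto one timeline.

The merged series has one row per gaze timestamp.  Head position is
linearly interpolated and head orientation spherically interpolated
(shortest-arc slerp) between the bracketing 120 Hz mocap samples.  Runs of
invalid gaze whose valid-to-valid bracket spans at most ``max_gaze_gap``
seconds (75 ms by default, inclusive) are filled by componentwise linear
interpolation of the direction followed by renormalization; longer runs
stay missing.  Gaze samples outside the head timeline are flagged invalid
rather than extrapolated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation, Slerp

from .recording import RawRecording, TrialRecording

__all__ = [
    "merge_streams",
    "segment_trials",
    "validity_fraction",
    "exclude_subject",
    "DEFAULT_MAX_GAZE_GAP",
    "VALIDITY_THRESHOLD",
]

DEFAULT_MAX_GAZE_GAP = 0.075
#: subjects with less than this fraction of valid gaze samples are dropped
VALIDITY_THRESHOLD = 0.65


def _interp_head(gaze_t: np.ndarray, head: pd.DataFrame):
    ht = head["t"].to_numpy(dtype=float)
    pos = head[["hx", "hy", "hz"]].to_numpy(dtype=float)
    quat = head[["qx", "qy", "qz", "qw"]].to_numpy(dtype=float)
    in_range = (gaze_t >= ht[0]) & (gaze_t <= ht[-1])
    t_clip = np.clip(gaze_t, ht[0], ht[-1])
    p = np.column_stack([np.interp(t_clip, ht, pos[:, a]) for a in range(3)])
    # slerp wants strictly increasing key times
    if len(ht) > 1:
        slerp = Slerp(ht, Rotation.from_quat(quat))
        q = slerp(t_clip).as_quat()
    else:
        q = np.repeat(quat, len(gaze_t), axis=0)
    return p, q, in_range


def _fill_gaps(t: np.ndarray, e: np.ndarray, valid: np.ndarray, max_gap: float):
    """Interpolate short invalid runs of the direction channel in place.

    Gap duration is measured from the last valid sample before the run to
    the first valid one after it (exclusive bracket); ties at exactly
    ``max_gap`` are interpolated.  Returns the fill mask.
    """
    filled = np.zeros(len(t), dtype=bool)
    n = len(t)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        if i > 0 and j < n and (t[j] - t[i - 1]) <= max_gap + 1e-12:
            for a in range(3):
                e[i:j, a] = np.interp(t[i:j], [t[i - 1], t[j]], [e[i - 1, a], e[j, a]])
            norms = np.linalg.norm(e[i:j], axis=1)
            ok = norms > 1e-12
            e[i:j][ok] /= norms[ok, None]
            filled[i:j] = ok
        i = j
    return filled


def merge_streams(
    recording: RawRecording,
    max_gaze_gap: float = DEFAULT_MAX_GAZE_GAP,
) -> pd.DataFrame:
    """One merged sample per gaze timestamp (columns as in
    :data:`activegaze.recording.MERGED_COLUMNS`)."""
    gaze = recording.gaze
    head = recording.head
    if len(gaze) == 0 or len(head) == 0:
        raise ValueError("both streams must be non-empty")
    t = gaze["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0) or np.any(np.diff(head["t"].to_numpy()) <= 0):
        raise ValueError("streams must be strictly time-sorted")

    e = gaze[["ex", "ey", "ez"]].to_numpy(dtype=float).copy()
    valid = (
        gaze["valid_left"].to_numpy(dtype=bool)
        & gaze["valid_right"].to_numpy(dtype=bool)
        & np.isfinite(e).all(axis=1)
        & (np.linalg.norm(np.nan_to_num(e), axis=1) > 1e-12)
    )
    norms = np.linalg.norm(np.nan_to_num(e), axis=1)
    e[valid] /= norms[valid, None]

    filled = _fill_gaps(t, e, valid, max_gaze_gap)
    valid = valid | filled
    e[~valid] = np.nan

    pos, quat, head_ok = _interp_head(t, head)
    valid = valid & head_ok

    return pd.DataFrame(
        {
            "t": t,
            "ex": e[:, 0], "ey": e[:, 1], "ez": e[:, 2],
            "hx": pos[:, 0], "hy": pos[:, 1], "hz": pos[:, 2],
            "qx": quat[:, 0], "qy": quat[:, 1], "qz": quat[:, 2], "qw": quat[:, 3],
            "valid": valid,
            "filled": filled,
        }
    )


def segment_trials(
    samples: pd.DataFrame,
    markers: pd.DataFrame,
    conditions: dict | None = None,
) -> list[TrialRecording]:
    """Cut the merged series into trials at the marker windows.

    Samples with t_start <= t <= t_end belong to the trial; everything
    outside every window is discarded.  Overlapping markers are an error;
    an empty window yields an empty trial plus a warning.
    """
    m = markers.sort_values("t_start").reset_index(drop=True)
    starts = m["t_start"].to_numpy(dtype=float)
    ends = m["t_end"].to_numpy(dtype=float)
    if np.any(ends[:-1] > starts[1:]):
        raise ValueError("trial markers overlap")
    t = samples["t"].to_numpy(dtype=float)
    trials = []
    for row, t0, t1 in zip(m.itertuples(), starts, ends):
        # nanosecond slack: marker times and sample grids may disagree by
        # one float ulp after serialization
        sel = samples[(t >= t0 - 1e-9) & (t <= t1 + 1e-9)].reset_index(drop=True)
        if len(sel) == 0:
            warnings.warn(f"trial {row.trial}: marker window contains no samples")
        trials.append(
            TrialRecording(
                trial_index=int(row.trial),
                samples=sel,
                t_start=float(t0),
                t_end=float(t1),
                response=str(row.response),
                condition=(conditions or {}).get(int(row.trial)),
            )
        )
    return trials


def validity_fraction(samples: pd.DataFrame, count_filled: bool = False) -> float:
    """Fraction of samples with valid gaze.

    By default gap-filled samples do not count as valid: the exclusion
    rule concerns the tracker's raw validity, before interpolation.
    """
    if len(samples) == 0:
        raise ValueError("empty sample list")
    valid = samples["valid"].to_numpy(dtype=bool)
    if not count_filled and "filled" in samples.columns:
        valid = valid & ~samples["filled"].to_numpy(dtype=bool)
    return float(valid.mean())


def exclude_subject(fraction: float, threshold: float = VALIDITY_THRESHOLD) -> bool:
    """Strictly-below-threshold exclusion rule (65 % by default)."""
    return fraction < threshold
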