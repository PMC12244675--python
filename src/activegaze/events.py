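"""I-VT event detection on the merged series.

Fixations are maximal runs of samples whose eye-in-head angular velocity
stays below a fixed threshold (30 deg/s); the runs between fixations are
saccades.  Velocity is the two-point estimate angle(e_i, e_{i+1}) / dt on
adjacent samples, with no smoothing window.  Runs of missing gaze break
events: no fixation or saccade spans a gap.

Each fixation is summarized by averaging over its samples: the arithmetic
mean head position, the normalized vector-mean eye-in-head direction, and
the orientation mean of the head quaternions (largest-eigenvector method
with hemisphere alignment, via scipy's rotation mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.transform import Rotation

from ._util import angle_between_deg, sd_outlier_mask
from .geometry import AmplitudeDecomposition, decompose_saccade
from .recording import TrialRecording

__all__ = [
    "EventConfig",
    "Fixation",
    "Saccade",
    "detect_fixations",
    "summarize_fixation",
    "remove_outliers",
    "fixation_duration_stats",
    "DurationStats",
]


@dataclass(frozen=True)
class EventConfig:
    """Detection parameters.

    velocity_threshold : deg/s, the I-VT boundary (30 deg/s).
    min_fixation_duration : s; runs shorter than this are discarded.  The
        default keeps 3 samples at 50 Hz.
    outlier_k : SD multiplier of the outlier rule.
    max_gaze_gap : s, the merge-stage interpolation limit (carried here
        for provenance).
    head_forward_axis : rigid-body forward axis used for head amplitudes.
    """

    velocity_threshold: float = 30.0
    min_fixation_duration: float = 0.06
    outlier_k: float = 3.0
    max_gaze_gap: float = 0.075
    head_forward_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0 or self.outlier_k <= 0:
            raise ValueError("velocity_threshold and outlier_k must be positive")


@dataclass
class Fixation:
    t_start: float
    t_end: float
    mean_eye_in_head: np.ndarray
    mean_head_position: np.ndarray
    mean_head_orientation: np.ndarray
    n_samples: int
    lookat_label: str | None = None
    is_target_fixation: bool = False

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Saccade:
    from_fixation: int
    to_fixation: int
    t_start: float
    t_end: float
    decomposition: AmplitudeDecomposition

    @property
    def eye_in_head_amp(self) -> float:
        return self.decomposition.eye_in_head_amp

    @property
    def head_amp(self) -> float:
        return self.decomposition.head_amp

    @property
    def eye_in_world_amp(self) -> float:
        return self.decomposition.eye_in_world_amp


def summarize_fixation(samples: pd.DataFrame) -> Fixation:
    """Average one fixation's samples into a single event.

    Mean gaze direction is the renormalized vector mean; head position the
    arithmetic mean; head orientation the quaternion mean (consistent
    hemisphere, largest eigenvector).
    """
    valid = samples[samples["valid"]] if "valid" in samples else samples
    if len(valid) == 0:
        raise ValueError("fixation window contains no valid samples")
    e = valid[["ex", "ey", "ez"]].to_numpy(dtype=float)
    mean_dir = e.mean(axis=0)
    norm = np.linalg.norm(mean_dir)
    if norm < 1e-12:
        raise ValueError("degenerate mean gaze direction")
    mean_dir = mean_dir / norm
    pos = valid[["hx", "hy", "hz"]].to_numpy(dtype=float).mean(axis=0)
    quats = valid[["qx", "qy", "qz", "qw"]].to_numpy(dtype=float)
    mean_q = Rotation.from_quat(quats).mean().as_quat()
    t = valid["t"].to_numpy(dtype=float)
    return Fixation(
        t_start=float(t[0]),
        t_end=float(t[-1]),
        mean_eye_in_head=mean_dir,
        mean_head_position=pos,
        mean_head_orientation=mean_q,
        n_samples=len(valid),
    )


def _valid_blocks(valid: np.ndarray):
    """Index ranges [i, j) of contiguous valid samples."""
    blocks = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        blocks.append((i, j))
        i = j
    return blocks


def sample_velocities(t: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Two-point angular velocity (deg/s) for each adjacent sample pair."""
    dt = np.diff(t)
    ang = angle_between_deg(e[:-1], e[1:])
    return np.asarray(ang) / dt


def detect_fixations(
    trial: TrialRecording | pd.DataFrame,
    config: EventConfig = EventConfig(),
) -> tuple[list[Fixation], list[Saccade]]:
    """Segment a trial into fixations and saccades (I-VT).

    Returns the fixations in time order and the saccades connecting
    consecutive fixations not separated by a missing-gaze run.
    """
    samples = trial.samples if isinstance(trial, TrialRecording) else trial
    valid = samples["valid"].to_numpy(dtype=bool)
    if valid.sum() < 2:
        warnings.warn("trial has fewer than 2 valid samples; no events")
        return [], []
    t = samples["t"].to_numpy(dtype=float)
    e = samples[["ex", "ey", "ez"]].to_numpy(dtype=float)

    fixations: list[Fixation] = []
    fixation_block: list[int] = []  # valid-block index per fixation
    for bi, (i, j) in enumerate(_valid_blocks(valid)):
        if j - i < 2:
            continue
        vel = sample_velocities(t[i:j], e[i:j])
        slow = vel < config.velocity_threshold
        k = 0
        while k < len(slow):
            if not slow[k]:
                k += 1
                continue
            m = k
            while m < len(slow) and slow[m]:
                m += 1
            # slow pairs k..m-1 cover samples k..m (block-relative); the
            # nanosecond slack guards against float cancellation at large
            # absolute timestamps
            if t[i + m] - t[i + k] >= config.min_fixation_duration - 1e-9:
                fixations.append(summarize_fixation(samples.iloc[i + k : i + m + 1]))
                fixation_block.append(bi)
            k = m
    saccades: list[Saccade] = []
    for a in range(len(fixations) - 1):
        if fixation_block[a] != fixation_block[a + 1]:
            continue  # a gap breaks the saccade
        dec = decompose_saccade(
            fixations[a],
            fixations[a + 1],
            forward_axis=np.asarray(config.head_forward_axis, dtype=float),
        )
        saccades.append(
            Saccade(
                from_fixation=a,
                to_fixation=a + 1,
                t_start=fixations[a].t_end,
                t_end=fixations[a + 1].t_start,
                decomposition=dec,
            )
        )
    return fixations, saccades


def remove_outliers(values, k: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, removed) by the |v - mean| > k*SD rule.

    Mean and sample SD come from one pass over the full input; the rule is
    not re-applied to the survivors.  Zero variance removes nothing.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    keep = sd_outlier_mask(values, k)
    return values[keep], values[~keep]


@dataclass(frozen=True)
class DurationStats:
    """Two-group fixation-duration comparison after outlier removal."""

    mean_target: float
    sd_target: float
    n_target: int
    mean_other: float
    sd_other: float
    n_other: int
    t: float
    df: int
    p: float


def fixation_duration_stats(
    durations: np.ndarray,
    is_target: np.ndarray,
    k: float = 3.0,
) -> DurationStats:
    """Compare target vs non-target fixation durations.

    The k-SD outlier rule is applied once to the pooled durations, then a
    pooled-variance two-sample t-test (df = n1 + n2 - 2) compares the
    groups.
    """
    durations = np.asarray(durations, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    keep = sd_outlier_mask(durations, k)
    durations, is_target = durations[keep], is_target[keep]
    tgt, oth = durations[is_target], durations[~is_target]
    if len(tgt) < 2 or len(oth) < 2:
        raise ValueError("both groups need at least 2 fixations")
    res = sps.ttest_ind(tgt, oth, equal_var=True)
    return DurationStats(
        mean_target=float(tgt.mean()), sd_target=float(tgt.std(ddof=1)), n_target=len(tgt),
        mean_other=float(oth.mean()), sd_other=float(oth.std(ddof=1)), n_other=len(oth),
        t=float(res.statistic), df=len(tgt) + len(oth) - 2, p=float(res.pvalue),
    )
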