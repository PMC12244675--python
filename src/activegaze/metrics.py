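"""Per-trial scalar metrics and layout-level hotspots.

The trial summary mirrors the behavioural measures of the search task:
response time, fixation counts split into look-at vs environment, 3D
distance travelled, revisit counts, response correctness and the index at
which the searcher left the start corner.  Hotspots are DBSCAN clusters of
fixation head positions on the floor plane, each carrying the histogram of
look-at labels produced from inside the cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .intersect import ENVIRONMENT, VisitSequence, count_revisits
from .recording import TrialRecording

__all__ = [
    "TrialMetrics",
    "Hotspot",
    "distance_travelled",
    "moved_out_of_start",
    "hotspots",
    "assemble_trial_metrics",
    "trial_metrics_frame",
]


@dataclass(frozen=True)
class TrialMetrics:
    """Scalar summary of one trial, the unit of the statistics layer."""

    trial_index: int
    response_time: float
    n_fixations: int
    n_lookat_fixations: int
    n_environment_fixations: int
    distance_travelled: float
    revisit_count: int
    unique_revisited: int
    correct: bool
    moved_out_index: int | None
    condition: object | None = None

    def __post_init__(self) -> None:
        if self.n_lookat_fixations + self.n_environment_fixations != self.n_fixations:
            raise ValueError("look-at + environment fixations must equal total")
        if self.distance_travelled < 0 or self.response_time <= 0:
            raise ValueError("distance must be >= 0 and response time > 0")


@dataclass(frozen=True)
class Hotspot:
    """One dense cluster of floor-plane head positions."""

    cluster_id: int
    member_points: np.ndarray            # (n, 2) head x-y
    lookat_histogram: dict[str, int]

    @property
    def centroid(self) -> np.ndarray:
        return self.member_points.mean(axis=0)


def distance_travelled(trial: TrialRecording | pd.DataFrame, variant: str = "track") -> float:
    """Total 3D path length of the head across the trial (m).

    ``variant="track"`` (the primary definition) sums Euclidean steps of
    the merged-rate head track after dropping missing poses;
    ``variant="hops"`` sums fixation-to-fixation displacements instead and
    exists for sensitivity checks (pass a DataFrame of fixation mean
    positions with columns hx, hy, hz).
    """
    samples = trial.samples if isinstance(trial, TrialRecording) else trial
    pos = samples[["hx", "hy", "hz"]].to_numpy(dtype=float)
    pos = pos[np.isfinite(pos).all(axis=1)]
    if len(pos) < 2:
        return 0.0
    if variant not in ("track", "hops"):
        raise ValueError("variant must be 'track' or 'hops'")
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def moved_out_of_start(fixations, threshold: float = 0.30) -> int | None:
    """1-based index of the first fixation > ``threshold`` m (strictly)
    from the first fixation's head position; None if the searcher never
    leaves the start."""
    if not fixations:
        raise ValueError("need at least one fixation")
    origin = np.asarray(fixations[0].mean_head_position, dtype=float)
    for i, f in enumerate(fixations, start=1):
        if np.linalg.norm(np.asarray(f.mean_head_position) - origin) > threshold:
            return i
    return None


def hotspots(
    head_points: np.ndarray,
    lookat_labels,
    eps: float = 0.15,
    min_frac: float = 0.02,
) -> list[Hotspot]:
    """Density clusters of fixation head positions (floor plane).

    DBSCAN with neighbourhood radius ``eps`` (m) and core threshold
    ceil(``min_frac`` * n_points), the 2 %-of-pooled-points reading of the
    clustering rule, floored at 2 so an isolated point is never a cluster.
    Returns one Hotspot per cluster with the look-at histogram of its
    member fixations; noise points belong to no cluster.
    """
    pts = np.asarray(head_points, dtype=float)[:, :2]
    labels = list(lookat_labels)
    if len(pts) != len(labels):
        raise ValueError("one look-at label per head point required")
    if len(pts) == 0:
        return []
    min_samples = max(2, math.ceil(min_frac * len(pts)))
    assignment = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pts)
    out = []
    for cid in sorted(set(assignment) - {-1}):
        sel = assignment == cid
        hist: dict[str, int] = {}
        for lab, s in zip(labels, sel):
            if s:
                hist[lab] = hist.get(lab, 0) + 1
        out.append(Hotspot(cluster_id=int(cid), member_points=pts[sel], lookat_histogram=hist))
    return out


def assemble_trial_metrics(
    trial: TrialRecording,
    fixations,
    saccades,
    visits: VisitSequence | None = None,
    response: str | None = None,
) -> TrialMetrics:
    """Collect one trial's scalar metrics.

    ``correct`` compares the (given or recorded) response against the trial
    condition's target presence; a "present" response on an absent trial is
    a false positive, an "absent" response on a present trial a false
    negative.
    """
    labels = [f.lookat_label for f in fixations]
    if visits is None:
        visits = count_revisits(labels)
    response = response if response is not None else trial.response
    n_fix = len(fixations)
    n_env = sum(1 for lab in labels if lab in (ENVIRONMENT, None))
    cond = trial.condition
    correct = True
    if cond is not None:
        expected = "present" if cond.target_present else "absent"
        correct = response == expected
    return TrialMetrics(
        trial_index=trial.trial_index,
        response_time=trial.t_end - trial.t_start,
        n_fixations=n_fix,
        n_lookat_fixations=n_fix - n_env,
        n_environment_fixations=n_env,
        distance_travelled=distance_travelled(trial),
        revisit_count=visits.revisit_count,
        unique_revisited=visits.unique_revisited,
        correct=correct,
        moved_out_index=moved_out_of_start(fixations) if fixations else None,
        condition=cond,
    )


def trial_metrics_frame(metrics: list[TrialMetrics], extra: dict | None = None) -> pd.DataFrame:
    """Tabulate TrialMetrics (plus condition columns) for the stats layer."""
    rows = []
    for m in metrics:
        row = {
            "trial": m.trial_index,
            "response_time": m.response_time,
            "n_fixations": m.n_fixations,
            "n_lookat_fixations": m.n_lookat_fixations,
            "n_environment_fixations": m.n_environment_fixations,
            "distance": m.distance_travelled,
            "revisits": m.revisit_count,
            "unique_revisited": m.unique_revisited,
            "correct": m.correct,
            "moved_out_index": m.moved_out_index,
        }
        c = m.condition
        if c is not None:
            row.update(
                target_present=c.target_present,
                set_size=c.set_size,
                visible_from_start=c.visible_from_start,
                target_orientation=c.target_orientation,
                target_surface=c.target_surface,
            )
        if extra:
            row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)
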