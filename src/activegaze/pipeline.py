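"""End-to-end processing of one subject's recording.

Chains the measurement stages — merge, trial segmentation, I-VT event
detection, look-at classification, revisit counting, trial metrics — and
collects per-fixation rows (head Euler angles, relative elevation,
look-at label) for the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventConfig, Fixation, Saccade, detect_fixations
from .geometry import head_euler, relative_elevation, standing_height
from .intersect import classify_fixation, count_revisits
from .merge import exclude_subject, merge_streams, segment_trials, validity_fraction
from .metrics import assemble_trial_metrics, trial_metrics_frame
from .recording import RawRecording, TrialRecording
from .scene import Layout, surface_elevation

__all__ = ["SubjectResult", "process_recording"]


@dataclass
class SubjectResult:
    """Everything the analysis layer needs from one subject."""

    merged: pd.DataFrame
    trials: list[TrialRecording]
    fixations: list[list[Fixation]]
    saccades: list[list[Saccade]]
    metrics: pd.DataFrame
    fixation_table: pd.DataFrame
    validity: float
    excluded: bool
    standing_height: float


def process_recording(
    recording: RawRecording,
    layout: Layout,
    conditions: dict[int, object] | None = None,
    config: EventConfig = EventConfig(),
    target_flags: dict[int, list[bool]] | None = None,
    subject: int | None = None,
) -> SubjectResult:
    """Run the full measurement chain on one subject.

    ``conditions`` maps trial index to its TrialCondition; ``target_flags``
    optionally carries externally annotated is-target flags per trial
    (applied when their length matches the detected fixation count).
    """
    merged = merge_streams(recording, max_gaze_gap=config.max_gaze_gap)
    validity = validity_fraction(merged)
    excluded = exclude_subject(validity)
    trials = segment_trials(merged, recording.markers, conditions)
    stand = standing_height(merged.loc[merged["valid"], "hz"].to_numpy())

    all_fix, all_sacc, all_metrics, fix_rows = [], [], [], []
    for trial in trials:
        fixations, saccades = detect_fixations(trial, config)
        for f in fixations:
            f.lookat_label = classify_fixation(f, layout)
        flags = (target_flags or {}).get(trial.trial_index)
        if flags is not None and len(flags) == len(fixations):
            for f, fl in zip(fixations, flags):
                f.is_target_fixation = bool(fl)
        visits = count_revisits([f.lookat_label for f in fixations])
        if fixations:
            all_metrics.append(
                assemble_trial_metrics(trial, fixations, saccades, visits)
            )
        all_fix.append(fixations)
        all_sacc.append(saccades)
        cond = trial.condition
        for i, f in enumerate(fixations):
            eul = head_euler(f.mean_head_orientation)
            row = {
                "subject": subject if subject is not None else 0,
                "trial": trial.trial_index,
                "fixation": i + 1,
                "t_start": f.t_start,
                "duration": f.duration,
                "label": f.lookat_label,
                "is_target": f.is_target_fixation,
                "roll": eul.roll,
                "pitch": eul.pitch,
                "yaw": eul.yaw,
                "head_z": float(f.mean_head_position[2]),
                "rel_elevation": float(relative_elevation(f.mean_head_position[2], stand)),
            }
            if cond is not None:
                row["orientation"] = cond.target_orientation
                row["target_surface"] = cond.target_surface
                row["surface_elevation"] = (
                    surface_elevation(layout, cond.target_surface)
                    if cond.target_surface else np.nan
                )
            fix_rows.append(row)

    metrics = trial_metrics_frame(all_metrics, extra={"subject": subject} if subject is not None else None)
    return SubjectResult(
        merged=merged,
        trials=trials,
        fixations=all_fix,
        saccades=all_sacc,
        metrics=metrics,
        fixation_table=pd.DataFrame(fix_rows),
        validity=validity,
        excluded=excluded,
        standing_height=stand,
    )
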