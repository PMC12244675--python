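"""In-memory containers for raw and merged recordings.

A recording pairs two independently clocked streams plus trial markers:

* ``gaze``: the eye tracker's 50 Hz export — per sample a timestamp (s),
  the eye-in-head unit direction (``ex, ey, ez``), optionally the
  tracker's inferred 3D gaze point (``gx, gy, gz``) and per-eye validity
  flags (``valid_left``, ``valid_right``).
* ``head``: the motion-capture rigid body at 120 Hz — timestamp, position
  (``hx, hy, hz``) and scalar-last orientation quaternion
  (``qx, qy, qz, qw``).
* ``markers``: one row per trial with ``trial``, ``t_start``, ``t_end``
  and the verbal ``response`` ("present"/"absent").

All tables are plain pandas DataFrames with those documented columns, so
they round-trip losslessly through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

__all__ = ["RawRecording", "TrialRecording", "GAZE_COLUMNS", "HEAD_COLUMNS", "MARKER_COLUMNS"]

GAZE_COLUMNS = ["t", "ex", "ey", "ez", "gx", "gy", "gz", "valid_left", "valid_right"]
HEAD_COLUMNS = ["t", "hx", "hy", "hz", "qx", "qy", "qz", "qw"]
MARKER_COLUMNS = ["trial", "t_start", "t_end", "response"]

MERGED_COLUMNS = [
    "t", "ex", "ey", "ez", "hx", "hy", "hz", "qx", "qy", "qz", "qw",
    "valid", "filled",
]


@dataclass
class RawRecording:
    """Paired gaze/head streams and trial markers for one subject."""

    gaze: pd.DataFrame
    head: pd.DataFrame
    markers: pd.DataFrame
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, df, required in (
            ("gaze", self.gaze, ("t", "ex", "ey", "ez")),
            ("head", self.head, HEAD_COLUMNS),
            ("markers", self.markers, MARKER_COLUMNS),
        ):
            missing = [c for c in required if c not in df.columns]
            if missing:
                raise ValueError(f"{name} stream missing columns {missing}")
        for flag in ("valid_left", "valid_right"):
            if flag not in self.gaze.columns:
                self.gaze[flag] = True


@dataclass
class TrialRecording:
    """Merged samples falling inside one trial's marker window."""

    trial_index: int
    samples: pd.DataFrame
    t_start: float
    t_end: float
    response: str
    condition: Any | None = None
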