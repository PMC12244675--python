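"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["angle_between_deg", "normalize", "sd_outlier_mask", "wrap_deg"]


def normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Return ``v`` scaled to unit length along ``axis``.

    Raises ``ValueError`` on (near-)zero vectors: a zero gaze or forward
    direction is always a data error upstream.
    """
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray | float:
    """Angle between vectors in degrees, numerically stable near 0 and 180.

    Uses atan2(|u x v|, u . v) instead of arccos of the clipped dot product
    so that sub-micro-degree angles survive in float64.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cross = np.linalg.norm(np.cross(u, v), axis=-1)
    dot = np.sum(u * v, axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def sd_outlier_mask(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Boolean mask of values to KEEP under the |v - mean| > k*SD rule.

    Mean and sample SD are computed once on the full input (single pass,
    no re-iteration).  Zero-variance input keeps everything.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return np.ones(values.shape, dtype=bool)
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0.0:
        return np.ones(values.shape, dtype=bool)
    return np.abs(values - mean) <= k * sd


def wrap_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)
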