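"""Temporal smoothing of frame labels and polarization-onset calling.

Per-frame classifications of a time-lapse are noisy; a single
simultaneous pass of a window-3 majority vote (ends untouched) removes
isolated flips, after which the first after-onset frame of the smoothed
sequence is called as the polarization onset.  Onset errors are
expressed in seconds using each recording's frame interval; a recording
with no called onset is scored as if onset occurred one frame past the
end of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import label_frames

__all__ = ["PredictionSeries", "smooth_labels", "call_onset", "time_discrepancy"]


@dataclass
class PredictionSeries:
    """Raw and smoothed per-frame labels for one recording plus the
    called onset."""

    recording_id: str
    labels: np.ndarray
    smoothed: np.ndarray
    onset_idx: int | None
    frame_interval_s: float

    @property
    def n_frames(self) -> int:
        return len(self.labels)


def _check_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return arr.astype(int)


def smooth_labels(labels, window: int = 3) -> np.ndarray:
    """Majority vote of the raw labels in a sliding odd window, computed
    in one simultaneous pass; both end labels are kept untouched."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    raw = _check_binary(labels)
    n = raw.size
    if n <= 2:
        return raw.copy()
    half = window // 2
    out = raw.copy()
    for i in range(1, n - 1):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = 1 if raw[lo:hi].sum() * 2 > (hi - lo) else 0
    return out


def call_onset(smoothed_labels):
    """Index of the first after-onset label, or None if never positive.

    Downstream relabelling uses ``label_frames(onset, n)``, so any
    anomalous pre-onset positives are overwritten once onset is called.
    """
    arr = _check_binary(smoothed_labels)
    hits = np.flatnonzero(arr == 1)
    return int(hits[0]) if hits.size else None


def relabel_from_onset(smoothed_labels) -> np.ndarray:
    """Labels implied by the called onset (monotone 0 -> 1 series)."""
    arr = _check_binary(smoothed_labels)
    return label_frames(call_onset(arr), arr.size)


def time_discrepancy(pred_idx, true_idx, frame_interval_s: float, n_frames: int) -> int:
    """Signed onset error in seconds, rounded to the nearest second.

    A missing prediction falls back to the frame immediately after the
    final frame (index ``n_frames``).
    """
    if true_idx is None:
        raise ValueError("annotated onset index is required")
    if not 0 <= true_idx < n_frames:
        raise ValueError(f"true onset {true_idx} outside recording of {n_frames} frames")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    effective = n_frames if pred_idx is None else pred_idx
    return int(round((effective - true_idx) * frame_interval_s))
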