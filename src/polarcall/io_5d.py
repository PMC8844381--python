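"""Reading and writing 5-D embryo recordings and frame label tables.

A recording is a single multi-dimensional TIFF with internal axis order
(t, z, c, y, x): time, optical section, channel, row, column.  Timing
and z-spacing metadata travel in a JSON sidecar (``<stem>.json``) next
to the TIFF; OME-style axis annotations on the TIFF are honoured when
present so externally produced files with permuted or missing axes can
be ingested.  Labels are plain CSV tables mapping (recording, frame) to
a before/after polarization-onset class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Recording5D",
    "LabelTable",
    "read_recording",
    "write_recording",
    "read_labels",
    "write_labels",
]

AXES = "tzcyx"
LABELS = ("before", "after")


@dataclass
class Recording5D:
    """One embryo time-lapse: intensities with axes (t, z, c, y, x)."""

    id: str
    tensor: np.ndarray
    channel_roles: dict  # channel index -> "dic" | "fluorescence"
    frame_interval_s: float
    z_step_um: float

    def __post_init__(self):
        t = np.asarray(self.tensor)
        if t.ndim != 5:
            raise ValueError(f"tensor must be 5-D (t,z,c,y,x), got {t.ndim}-D")
        if min(t.shape) < 1:
            raise ValueError("all five axis lengths must be >= 1")
        if not np.all(np.isfinite(t)):
            raise ValueError("tensor values must be finite")
        if t.min() < 0:
            raise ValueError("tensor values must be nonnegative")
        roles = {int(k): v for k, v in self.channel_roles.items()}
        if sorted(roles.values()) != sorted(set(roles.values())):
            raise ValueError("channel_roles must assign each role to exactly one channel")
        for c, role in roles.items():
            if role not in ("dic", "fluorescence"):
                raise ValueError(f"unknown channel role {role!r}")
            if not 0 <= c < t.shape[2]:
                raise ValueError(f"channel index {c} outside tensor channel axis")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if not self.z_step_um > 0:
            raise ValueError("z_step_um must be positive")
        self.tensor = t
        self.channel_roles = roles

    @property
    def n_frames(self) -> int:
        return self.tensor.shape[0]

    def channel_index(self, role: str) -> int:
        for c, r in self.channel_roles.items():
            if r == role:
                return c
        raise KeyError(f"recording {self.id!r} has no channel with role {role!r}")

    def frame_time_s(self, idx: int) -> float:
        """Time of frame ``idx`` (0-based) from the start of the recording."""
        return idx * self.frame_interval_s


@dataclass
class LabelTable:
    """Frame-level before/after labels, one row per (recording, frame)."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["recording_id", "frame_index", "label"]
        )
    )

    def __post_init__(self):
        df = self.frame.copy()
        df["frame_index"] = df["frame_index"].astype(int)
        bad = ~df["label"].isin(LABELS)
        if bad.any():
            raise ValueError(
                f"labels must be in {LABELS}, found {sorted(df.loc[bad, 'label'].unique())}"
            )
        if df.duplicated(["recording_id", "frame_index"]).any():
            raise ValueError("duplicate (recording_id, frame_index) rows")
        self.frame = df.reset_index(drop=True)

    def binary(self, recording_id: str) -> np.ndarray:
        """0/1 labels for one recording, ordered by frame index."""
        sub = self.frame[self.frame.recording_id == recording_id].sort_values(
            "frame_index"
        )
        return (sub.label.to_numpy() == "after").astype(int)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording5D, path) -> None:
    """Write a recording as a TZCYX TIFF plus JSON metadata sidecar."""
    path = Path(path)
    try:
        tifffile.imwrite(path, rec.tensor, metadata={"axes": "TZCYX"})
    except OSError as e:
        raise OSError(f"cannot write recording to {path}: {e}") from e
    meta = {
        "id": rec.id,
        "frame_interval_s": rec.frame_interval_s,
        "z_step_um": rec.z_step_um,
        "channel_roles": {str(k): v for k, v in rec.channel_roles.items()},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_recording(path, axis_order: str | None = None, metadata: dict | None = None) -> Recording5D:
    """Read a TIFF recording, permuting/inserting axes to (t,z,c,y,x).

    axis_order overrides the axes stored in the file; it must be a
    subset-permutation of "tzcyx" (missing axes must have length 1 in
    the file and are inserted).  metadata entries override the sidecar.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            file_axes = tif.series[0].axes.lower() if tif.series else ""
    except (OSError, ValueError) as e:
        raise OSError(f"cannot read recording from {path}: {e}") from e

    if axis_order is not None:
        axes = axis_order.lower()
    else:
        # tifffile reports samples-per-pixel as 's'; treat it as channel
        axes = file_axes.replace("s", "c")
    for a in axes:
        if a not in AXES:
            raise ValueError(f"unknown axis {a!r} in axis order {axes!r}")
    if len(set(axes)) != len(axes):
        raise ValueError(f"repeated axis in axis order {axes!r}")
    if len(axes) != data.ndim:
        raise ValueError(
            f"axis order {axes!r} has {len(axes)} axes but data is {data.ndim}-D"
        )

    # permute present axes into tzcyx order, then insert missing ones
    present = [a for a in AXES if a in axes]
    data = np.transpose(data, [axes.index(a) for a in present])
    for i, a in enumerate(AXES):
        if a not in axes:
            data = np.expand_dims(data, i)

    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    if metadata:
        meta.update(metadata)
    roles = meta.get("channel_roles")
    if roles is None:
        roles = {0: "dic"} if data.shape[2] == 1 else {0: "dic", 1: "fluorescence"}
    return Recording5D(
        id=meta.get("id", path.stem),
        tensor=data,
        channel_roles={int(k): v for k, v in dict(roles).items()},
        frame_interval_s=float(meta.get("frame_interval_s", 1200.0)),
        z_step_um=float(meta.get("z_step_um", 4.0)),
    )


def read_labels(path) -> LabelTable:
    df = pd.read_csv(path, dtype={"recording_id": str})
    missing = {"recording_id", "frame_index", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"label CSV {path} missing columns {sorted(missing)}")
    return LabelTable(df[["recording_id", "frame_index", "label"]])


def write_labels(table: LabelTable, path) -> None:
    table.frame.to_csv(path, index=False)
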