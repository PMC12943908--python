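"""Domain types and file I/O for IMU records, stride events and estimates.

The on-disk formats are deliberately plain: IMU logs are headered CSV
(time, ax, ay, az by default), stride events are one integer sample index
per line, and per-stride estimates are a small CSV table. Stride cycles are
delimited by consecutive event indices; segment intervals are half-open
``[start, end)`` so strides tile the record without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImuSequence",
    "StrideEventIndex",
    "StrideSegment",
    "StrideEstimate",
    "read_imu_csv",
    "write_imu_csv",
    "read_stride_events",
    "write_stride_events",
    "segment_strides",
    "read_estimates",
    "write_estimates",
]

#: time tolerance (s) when validating uniform sampling against dt
_DT_TOL = 1e-6

AXES = ("ax", "ay", "az")


@dataclass
class ImuSequence:
    """A uniformly sampled tri-axial acceleration record.

    Parameters
    ----------
    ax, ay, az
        Acceleration channels in m/s² (after any unit conversion applied
        at read time).
    dt
        Sampling interval in seconds; the sensor's is 0.02 s (50 Hz).
    timestamps
        Optional time stamps in seconds. If absent they are synthesized
        as ``k * dt`` on demand. If present they must be uniform with
        step ``dt`` to within 1e-6 s.
    channel_meta
        Free-text unit/axis annotations.
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    dt: float = 0.02
    timestamps: np.ndarray | None = None
    channel_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("acceleration channels must have identical length")
        if len(self.ax) < 1:
            raise ValueError("empty sequence")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.timestamps is not None:
            t = np.asarray(self.timestamps, dtype=float)
            if len(t) != len(self.ax):
                raise ValueError("timestamps length does not match channels")
            if len(t) > 1:
                steps = np.diff(t)
                if np.max(np.abs(steps - self.dt)) >= _DT_TOL:
                    raise ValueError(
                        "sampling-interval mismatch: timestamps do not step "
                        f"uniformly by dt={self.dt}"
                    )
            self.timestamps = t

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def times(self) -> np.ndarray:
        if self.timestamps is not None:
            return self.timestamps
        return np.arange(len(self)) * self.dt

    def channel(self, name: str) -> np.ndarray:
        if name not in AXES:
            raise ValueError(f"unknown channel {name!r}; expected one of {AXES}")
        return getattr(self, name)


@dataclass
class StrideEventIndex:
    """Ordered gait-event sample indices; consecutive pairs delimit strides."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1 or len(idx) < 2:
            raise ValueError("fewer than 2 indices: at least one stride is required")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("event indices must be strictly increasing")
        if idx[0] < 0:
            raise ValueError("negative event index")
        self.indices = idx

    def validate_against(self, n_samples: int) -> None:
        if self.indices[-1] > n_samples - 1:
            raise ValueError(
                f"index out of range: {self.indices[-1]} exceeds last valid "
                f"sample index {n_samples - 1}"
            )

    @property
    def n_strides(self) -> int:
        return len(self.indices) - 1


@dataclass
class StrideSegment:
    """One stride's slice of a measurement channel, interval ``[start, end)``."""

    stride_id: int
    start: int
    end: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.end - self.start < 3:
            raise ValueError("segment shorter than 3 samples")
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) != self.end - self.start:
            raise ValueError("samples length does not match [start, end)")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class StrideEstimate:
    """A per-stride length estimate, optionally paired with its reference.

    ``error_percent`` is the relative error |actual − predicted| / |actual|
    × 100 and exists exactly when a nonzero reference length is present.
    """

    stride_id: int
    estimated_length: float
    reference_length: float | None = None
    error_percent: float | None = None

    def __post_init__(self) -> None:
        if self.estimated_length < 0:
            raise ValueError("estimated_length must be non-negative")
        has_ref = self.reference_length is not None and self.reference_length != 0
        if has_ref and self.error_percent is None:
            self.error_percent = (
                abs(self.reference_length - self.estimated_length)
                / abs(self.reference_length)
                * 100.0
            )
        if not has_ref:
            self.error_percent = None


def read_imu_csv(
    path: str | Path,
    dt: float = 0.02,
    column_map: dict | None = None,
    scale: float = 1.0,
) -> ImuSequence:
    """Read an IMU log CSV into an :class:`ImuSequence`.

    ``column_map`` maps canonical names (``time``, ``ax``, ``ay``, ``az``)
    to the file's column names; ``time`` may be omitted. ``scale`` is the
    unit-conversion factor applied to all three channels (e.g. 9.81 for
    logs recorded in g).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = {"time": "time", "ax": "ax", "ay": "ay", "az": "az"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    if len(df) < 1:
        raise ValueError("empty sequence: IMU file contains no data rows")
    channels = {}
    for canon in AXES:
        col = cmap[canon]
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path.name}")
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(
                f"non-numeric cell in column {col!r} at data row {row}"
            )
        channels[canon] = vals.to_numpy(dtype=float) * scale
    timestamps = None
    tcol = cmap.get("time")
    if tcol is not None and tcol in df.columns:
        tvals = pd.to_numeric(df[tcol], errors="coerce")
        if tvals.isna().any():
            row = int(tvals.index[tvals.isna()][0])
            raise ValueError(f"non-numeric cell in column {tcol!r} at data row {row}")
        timestamps = tvals.to_numpy(dtype=float)
    return ImuSequence(dt=dt, timestamps=timestamps, **channels)


def write_imu_csv(path: str | Path, seq: ImuSequence) -> None:
    df = pd.DataFrame(
        {"time": seq.times, "ax": seq.ax, "ay": seq.ay, "az": seq.az}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_stride_events(
    path: str | Path, n_samples: int, one_based: bool = False
) -> StrideEventIndex:
    """Read a stride-event file (one integer index per line).

    ``one_based`` converts 1-based indices to the package's 0-based
    convention on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    values = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip().rstrip(",")
        if not line:
            continue
        try:
            values.append(int(line.split(",")[0]))
        except ValueError as exc:
            raise ValueError(f"non-integer event index on line {lineno}") from exc
    if len(values) < 2:
        raise ValueError("fewer than 2 indices: cannot define a stride")
    idx = np.asarray(values, dtype=int)
    if one_based:
        idx = idx - 1
    events = StrideEventIndex(idx)
    events.validate_against(n_samples)
    return events


def write_stride_events(path: str | Path, events: StrideEventIndex) -> None:
    Path(path).write_text("\n".join(str(int(i)) for i in events.indices) + "\n")


def segment_strides(
    seq: ImuSequence, events: StrideEventIndex, channel: str = "az"
) -> list[StrideSegment]:
    """Cut one measurement channel into per-stride half-open segments.

    Segment ``i`` spans ``[indices[i], indices[i+1])``; concatenating all
    segments reproduces ``seq[indices[0]:indices[-1]]`` on that channel.
    """
    events.validate_against(len(seq))
    data = seq.channel(channel)
    segments = []
    for i, (a, b) in enumerate(zip(events.indices[:-1], events.indices[1:])):
        segments.append(
            StrideSegment(stride_id=i, start=int(a), end=int(b), samples=data[a:b])
        )
    return segments


_EST_COLUMNS = ["stride_id", "estimated_length", "reference_length", "error_percent"]


def write_estimates(path: str | Path, estimates: Sequence[StrideEstimate]) -> None:
    rows = [
        {
            "stride_id": e.stride_id,
            "estimated_length": e.estimated_length,
            "reference_length": e.reference_length,
            "error_percent": e.error_percent,
        }
        for e in estimates
    ]
    # %.17g guarantees exact float round-trip through the text format
    pd.DataFrame(rows, columns=_EST_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_estimates(path: str | Path) -> list[StrideEstimate]:
    df = pd.read_csv(path)
    for col in _EST_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in estimates file")
    out = []
    for _, row in df.iterrows():
        ref = row["reference_length"]
        ref = None if pd.isna(ref) else float(ref)
        err = row["error_percent"]
        err = None if pd.isna(err) else float(err)
        out.append(
            StrideEstimate(
                stride_id=int(row["stride_id"]),
                estimated_length=float(row["estimated_length"]),
                reference_length=ref,
                error_percent=err,
            )
        )
    return out
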