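"""Reading and writing uniformly sampled skin conductance recordings.

Plain delimited text only: a recording is a CSV with a time column (seconds,
strictly increasing, uniform) and a conductance column (microsiemens).
Column names are configurable through a ``column_spec`` mapping so that
exports from different wearable devices can be read without bespoke code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["Recording", "read_recording", "write_series", "FLOAT_FORMAT"]

#: Round-trip-safe text formatting (>= 10 significant digits).
FLOAT_FORMAT = "%.12g"

DEFAULT_COLUMNS = {"time": "time", "conductance": "conductance"}

#: Annotation: (label, start s, end s).
Annotation = tuple[str, float, float]


@dataclass
class Recording:
    """A uniformly sampled skin conductance recording."""

    subject_id: str
    samples: np.ndarray
    sampling_interval: float
    start_time: float = 0.0
    annotations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        t0, t1 = self.start_time, self.start_time + self.duration
        for label, a, b in self.annotations:
            if not (t0 <= a <= b <= t1):
                raise ValueError(
                    f"annotation {label!r} [{a}, {b}] outside [{t0}, {t1}]"
                )

    @property
    def duration(self) -> float:
        """Covered time span (left-closed, right-open grid)."""
        return self.samples.size * self.sampling_interval

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) * \
            self.sampling_interval


def read_recording(
    path: Union[str, Path],
    column_spec: Optional[Mapping[str, str]] = None,
    subject_id: Optional[str] = None,
    uniformity_tol: float = 0.01,
) -> Recording:
    """Read a two-column delimited recording.

    The sampling interval is the median successive time difference; reading
    fails if any step deviates from it by more than ``uniformity_tol``
    (relative), if the time column is not strictly increasing, or if fewer
    than 2 rows are present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spec = {**DEFAULT_COLUMNS, **(column_spec or {})}
    df = pd.read_csv(path)
    for role in ("time", "conductance"):
        if spec[role] not in df.columns:
            raise ValueError(f"missing {role} column {spec[role]!r}")
    if len(df) < 2:
        raise ValueError("recording needs at least 2 rows")
    t = pd.to_numeric(df[spec["time"]], errors="raise").to_numpy(dtype=float)
    y = pd.to_numeric(df[spec["conductance"]], errors="raise").to_numpy(
        dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > uniformity_tol * step:
        raise ValueError("non-uniform sampling beyond tolerance")
    return Recording(
        subject_id=subject_id or path.stem,
        samples=y,
        sampling_interval=step,
        start_time=float(t[0]),
    )


def write_series(
    path: Union[str, Path],
    series: Mapping[str, Sequence[float]],
) -> None:
    """Write named, equal-length series as deterministic delimited text.

    The first column is conventionally the shared time base; values survive
    a text round trip to at least 10 significant digits.
    """
    if not series:
        raise ValueError("no series to write")
    lengths = {name: len(np.asarray(col)) for name, col in series.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"mismatched series lengths: {lengths}")
    df = pd.DataFrame({name: np.asarray(col) for name, col in series.items()})
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
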