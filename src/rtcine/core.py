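"""Core in-memory containers for real-time cardiac MRI binning.

The pipeline operates on three containers: :class:`RTFrame` (one real-time
image with its cardiac and acquisition timing tags), :class:`RTSeries`
(the ordered free-breathing frame stream, grouped per slice) and
:class:`BinnedStack` (the retrospectively binned 25-phase cine result).
A fourth, :class:`PhysioTrace`, holds the respiratory-bellows signal.

Timing convention: all times are milliseconds on a single acquisition
clock starting at the first frame of the series.  ``trigger_time`` is the
ECG-derived time since the last R wave, as delivered by the scanner in
the DICOM Trigger Time tag.  Bellows values are arbitrary units on a
[0, 4000] working scale (see :mod:`rtcine.physio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RTFrame", "RTSeries", "PhysioTrace", "BinnedStack", "BinResult"]


@dataclass
class RTFrame:
    """A single real-time frame with its timing and geometry tags."""

    pixels: np.ndarray              # 2-D non-negative integer grid
    acq_time: float                 # ms since series start
    trigger_time: float             # ms since last R wave
    slice_index: int = 0
    slice_location: float = 0.0     # mm
    pixel_spacing: tuple[float, float] = (1.0, 1.0)   # mm/px (row, col)
    slice_thickness: float = 8.0    # mm
    bellows: float | None = None    # a.u. in [0, 4000], None until assigned

    def __post_init__(self) -> None:
        if self.trigger_time < 0:
            raise ValueError(f"trigger_time must be >= 0, got {self.trigger_time}")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")


@dataclass
class RTSeries:
    """One free-breathing real-time acquisition: per-slice frame lists.

    ``frames[i]`` is the time-ordered frame list of slice ``i`` (base to
    apex by ascending slice index).  Frames of one slice share their
    slice location and matrix size.
    """

    frames: list[list[RTFrame]]
    frame_rate: float = 30.0        # frames / s
    duration: float = 30.0          # s per slice

    @property
    def n_slices(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        if not self.frames or not any(self.frames):
            raise ValueError("series contains no frames")
        shape = self.frames[0][0].pixels.shape
        for sl in self.frames:
            if not sl:
                raise ValueError("series has an empty slice")
            locs = {round(f.slice_location, 2) for f in sl}
            if len(locs) != 1:
                raise ValueError("frames of one slice disagree on slice location")
            times = [f.acq_time for f in sl]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError("acq_time not strictly increasing within a slice")
            for f in sl:
                if f.pixels.shape != shape:
                    raise ValueError("inconsistent matrix sizes within series")

    def all_frames(self) -> list[RTFrame]:
        return [f for sl in self.frames for f in sl]


@dataclass
class PhysioTrace:
    """Respiratory-bellows trace: strictly increasing timestamps (ms), a.u. values."""

    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.size != self.values.size:
            raise ValueError("timestamps and values differ in length")
        if self.timestamps.size < 2:
            raise ValueError("physio trace needs at least 2 samples")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("physio timestamps must be strictly increasing")

    @property
    def sample_rate(self) -> float:
        """Hz, derived from the median sampling interval."""
        return 1000.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class BinResult:
    """Per-bin bookkeeping from the binning step (for logs and manifests)."""

    slice_index: int
    phase: int
    n_candidates: int       # frames whose trigger time falls in the phase window
    n_gated: int            # of those, frames passing the respiratory gate
    chosen_bellows: float
    fallback: bool          # True if the gate had to be relaxed for this bin


@dataclass
class BinnedStack:
    """Retrospectively binned cine stack: exactly ``n_phases`` frames per slice.

    ``frames[i][k]`` is the representative frame of slice ``i`` at cardiac
    phase ``k``; its trigger time lies in ``[k*w, (k+1)*w)`` for
    ``w = phase_duration``.
    """

    frames: list[list[RTFrame]]
    phase_duration: float                       # ms per phase bin
    fallback_flags: list[list[bool]]
    bin_results: list[BinResult] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return len(self.frames)

    @property
    def n_phases(self) -> int:
        return len(self.frames[0]) if self.frames else 0

    def validate(self) -> None:
        if not self.frames:
            raise ValueError("empty stack")
        n = self.n_phases
        w = self.phase_duration
        for i, sl in enumerate(self.frames):
            if len(sl) != n:
                raise ValueError(f"slice {i} has {len(sl)} phases, expected {n}")
            for k, f in enumerate(sl):
                if not (k * w <= f.trigger_time < (k + 1) * w):
                    raise ValueError(
                        f"slice {i} phase {k}: trigger {f.trigger_time} outside bin"
                    )
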