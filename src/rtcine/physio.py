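"""Respiratory-bellows preprocessing and frame synchronization.

The bellows belt produces a 1-D arbitrary-unit signal roughly
proportional to respiratory excursion.  Before it can drive the
respiratory gate it is (1) low-pass filtered with a zero-phase
Butterworth filter, (2) rescaled to a fixed [0, 4000] a.u. working
scale using robust percentiles, and (3) interpolated onto each frame's
acquisition time.  On the working scale the expiratory gate sits at
half range (< 2000 a.u.) and the representative-frame target at a
quarter range (1000 a.u.); see :mod:`rtcine.binning`.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

from .core import PhysioTrace, RTSeries

__all__ = [
    "denoise_bellows",
    "normalize_bellows",
    "assign_bellows_to_frames",
    "preprocess_trace",
    "SCALE_MAX",
]

SCALE_MAX = 4000.0  # a.u. ceiling of the normalized working scale


def denoise_bellows(trace: PhysioTrace, cutoff_hz: float = 1.0, order: int = 4) -> PhysioTrace:
    """Zero-phase low-pass Butterworth filter; timestamps unchanged.

    Applied forward-backward (``filtfilt``) so the gate is not delayed
    relative to the frames.  Raises if the cutoff is at or above the
    Nyquist frequency of the trace.
    """
    fs = trace.sample_rate
    nyq = fs / 2.0
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq:.3g} Hz")
    b, a = butter(order, cutoff_hz / nyq, btype="low")
    filtered = filtfilt(b, a, trace.values)
    return PhysioTrace(trace.timestamps.copy(), filtered)


def normalize_bellows(trace: PhysioTrace, scale_max: float = SCALE_MAX) -> PhysioTrace:
    """Robust min-max rescale: 1st/99th percentiles map to 0/``scale_max``.

    Values beyond the percentiles are clipped, so isolated spikes cannot
    stretch the scale.  A trace without respiratory excursion (constant)
    is rejected.
    """
    lo, hi = np.percentile(trace.values, [1.0, 99.0])
    if hi <= lo:
        raise ValueError("no respiratory excursion in bellows trace")
    scaled = (trace.values - lo) / (hi - lo) * scale_max
    return PhysioTrace(trace.timestamps.copy(), np.clip(scaled, 0.0, scale_max))


def assign_bellows_to_frames(
    trace: PhysioTrace, series: RTSeries, offset_ms: float = 0.0
) -> RTSeries:
    """Assign each frame the bellows value at its acquisition time.

    The trace is shifted by ``offset_ms`` (constant clock offset between
    the physio logger and the frame clock) and linearly interpolated at
    each frame's ``acq_time``.  Frames outside the shifted trace's time
    range are a hard error: extrapolated gating is never silent.
    Mutates and returns ``series``.
    """
    t0 = trace.timestamps[0] - offset_ms
    t1 = trace.timestamps[-1] - offset_ms
    bad = [
        (si, fi)
        for si, sl in enumerate(series.frames)
        for fi, f in enumerate(sl)
        if not (t0 <= f.acq_time <= t1)
    ]
    if bad:
        raise ValueError(
            f"{len(bad)} frame(s) outside physio coverage, first (slice, frame): {bad[0]}"
        )
    for sl in series.frames:
        times = np.array([f.acq_time for f in sl]) + offset_ms
        vals = np.interp(times, trace.timestamps, trace.values)
        for f, v in zip(sl, vals):
            f.bellows = float(v)
    return series


def preprocess_trace(
    trace: PhysioTrace,
    cutoff_hz: float = 1.0,
    order: int = 4,
    scale_max: float = SCALE_MAX,
) -> PhysioTrace:
    """Denoise then normalize — the standard preprocessing chain."""
    return normalize_bellows(denoise_bellows(trace, cutoff_hz, order), scale_max)
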