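"""Retrospective cardiac-phase binning with respiratory gating.

The core algorithm: every free-breathing real-time frame carries the
ECG-derived time since the last R wave (trigger time) and, after
synchronization, a respiratory-bellows value.  One mean heart cycle is
divided into ``n_phases`` equal half-open windows of width
``mean_rr / n_phases``.  Within each window, frames at low lung volume
(bellows below the gate threshold, default 2000 a.u.) compete, and the
frame whose bellows value is closest to the expiratory class median
(default 1000 a.u.) is kept as the representative of that phase.  The
result is one quiescent-respiration cine cycle per slice.

Frames with trigger time at or beyond the mean RR interval (long beats)
are discarded.  If a phase window contains frames but none passes the
gate, the gate is relaxed for that bin and the bin is flagged
(``allow_fallback``), since a 30-s acquisition cannot guarantee every
phase x expiration combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinnedStack, BinResult, RTFrame, RTSeries

__all__ = [
    "BinConfig",
    "phase_width",
    "phase_index",
    "gate_frames",
    "select_representative",
    "bin_series",
    "estimate_mean_rr",
]


@dataclass
class BinConfig:
    """Parameters of the gating + binning step.

    mean_rr is the patient's mean R-R interval in ms; it defines the
    reconstructed cycle length and is chosen per patient.
    """

    mean_rr: float
    n_phases: int = 25
    gate_threshold: float = 2000.0   # a.u., strict upper bound for the gate
    median_target: float = 1000.0    # a.u., expiratory-class median
    allow_fallback: bool = True

    def __post_init__(self) -> None:
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if not (0 < self.median_target < self.gate_threshold):
            raise ValueError("need 0 < median_target < gate_threshold")


def phase_width(config: BinConfig) -> float:
    """Duration of one cardiac phase bin: ``mean_rr / n_phases`` (ms)."""
    return config.mean_rr / config.n_phases


def phase_index(trigger_time: float, config: BinConfig) -> int | None:
    """Phase bin of a trigger time, or None for long-beat frames.

    Bins are half-open: phase ``k`` covers ``[k*w, (k+1)*w)``.  Trigger
    times at or beyond ``mean_rr`` fall outside the reconstructed cycle
    and return None.
    """
    if trigger_time < 0:
        raise ValueError(f"negative trigger time {trigger_time}")
    if trigger_time >= config.mean_rr:
        return None
    k = int(trigger_time // phase_width(config))
    # floating-point guard at the upper edge
    return min(k, config.n_phases - 1)


def gate_frames(frames: list[RTFrame], config: BinConfig) -> list[RTFrame]:
    """Keep exactly the frames with bellows strictly below the gate threshold."""
    for f in frames:
        if f.bellows is None:
            raise ValueError("frame without assigned bellows value")
    return [f for f in frames if f.bellows < config.gate_threshold]


def select_representative(candidates: list[RTFrame], config: BinConfig) -> RTFrame:
    """Frame minimizing |bellows - median_target|; ties go to earliest acq_time."""
    if not candidates:
        raise ValueError("no candidate frames")
    return min(
        candidates,
        key=lambda f: (abs(f.bellows - config.median_target), f.acq_time),
    )


def bin_series(series: RTSeries, config: BinConfig) -> BinnedStack:
    """Bin a synchronized series into ``n_phases`` representative frames per slice.

    For each slice and phase window: gather the frames whose trigger
    time falls in the window, apply the respiratory gate, and pick the
    representative.  An empty window (even before gating) means the
    acquisition does not cover that phase and is a hard error; an empty
    *gated* window falls back to the ungated candidates (flagged) when
    ``allow_fallback`` is set, and errors otherwise.
    """
    series.validate()
    w = phase_width(config)
    out_frames: list[list[RTFrame]] = []
    flags: list[list[bool]] = []
    results: list[BinResult] = []
    for si, sl in enumerate(series.frames):
        by_phase: list[list[RTFrame]] = [[] for _ in range(config.n_phases)]
        for f in sl:
            k = phase_index(f.trigger_time, config)
            if k is not None:
                by_phase[k].append(f)
        slice_frames, slice_flags = [], []
        for k, candidates in enumerate(by_phase):
            if not candidates:
                raise ValueError(
                    f"insufficient coverage: slice {si} phase {k} has no frames"
                )
            gated = gate_frames(candidates, config)
            if gated:
                chosen = select_representative(gated, config)
                fallback = False
            elif config.allow_fallback:
                chosen = select_representative(candidates, config)
                fallback = True
            else:
                raise ValueError(
                    f"slice {si} phase {k}: no frame passes the respiratory gate"
                )
            slice_frames.append(chosen)
            slice_flags.append(fallback)
            results.append(
                BinResult(si, k, len(candidates), len(gated), chosen.bellows, fallback)
            )
        out_frames.append(slice_frames)
        flags.append(slice_flags)
    return BinnedStack(
        frames=out_frames, phase_duration=w, fallback_flags=flags, bin_results=results
    )


def estimate_mean_rr(series: RTSeries) -> float:
    """Mean R-R interval (ms) reconstructed from trigger-time resets.

    A drop in trigger time between consecutive frames of one slice marks
    an R wave; the R-wave instant is ``acq_time - trigger_time`` of each
    frame, so successive resets yield exact R-R gaps.  Used when no
    per-patient mean RR is supplied.
    """
    gaps = []
    for sl in series.frames:
        r_times = []
        for prev, cur in zip(sl, sl[1:]):
            if cur.trigger_time < prev.trigger_time:
                r_times.append(cur.acq_time - cur.trigger_time)
        gaps.extend(np.diff(r_times))
    if not gaps:
        raise ValueError("no trigger-time resets found; cannot estimate mean RR")
    return float(np.mean(gaps))
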