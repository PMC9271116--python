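"""Seeded beating-and-breathing two-ventricle digital phantom.

The phantom emits exactly what the binning pipeline consumes: a
real-time short-axis frame stream (one stack of 2-D frames per slice,
each frame tagged with its acquisition time and ECG trigger time), a
respiratory-bellows trace, and the analytic ground truth (per-ventricle
EDV/ESV/SV/EF, the bellows function and the volume curve).

Model
-----
* R waves are drawn sequentially with R-R gaps ~ Normal(mean_rr, jitter),
  floored at 60% of the mean so pathological short beats cannot occur.
  The cardiac phase at time t is (t - last R) / current RR.
* The total blood-pool volume of each ventricle follows a raised-cosine
  curve between EDV (phase 0) and ESV (mid-cycle):
  ``v(phi) = ESV + (EDV - ESV) * (1 + cos(2*pi*phi')) / 2`` with the
  smooth phase warp ``phi' = (1 - cos(pi*phi)) / 2``.  The warp makes
  the curve flat near both extremes, as real volume curves are around
  end-diastole and end-systole.
* Volume is distributed over the slice stack with a fixed base-to-apex
  taper proportional to ``1 - 0.8 * z^2`` (z from 0 at the base to 1 at
  the apex), so per-slice cross-sectional areas are analytic.
* The left ventricle is a disc with a myocardial ring, the right
  ventricle a vertically elongated ellipse (axis ratio 0.6) with a thin
  rim; both are rendered with sub-pixel edge coverage.
* Respiration translates the whole heart rigidly along the image column
  axis: ``s(t) = resp_amp * (1 - cos(2*pi*t / resp_period)) / 2`` (zero
  displacement = end-expiration).  The bellows trace is
  ``4000 * s(t) / resp_amp`` plus Gaussian noise, sampled at 50 Hz.
* Slices are acquired sequentially, each for ``duration_s`` seconds, as
  in a slice-by-slice real-time protocol; the bellows trace spans the
  whole session.

All times are quantized to 1 µs so that DICOM round trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PhysioTrace, RTFrame, RTSeries

__all__ = [
    "PhantomConfig",
    "VentricleTruth",
    "GroundTruth",
    "simulate_acquisition",
    "ground_truth_volumes",
    "analysis_regions",
]

_PHYSIO_RATE_HZ = 50.0


@dataclass
class PhantomConfig:
    """Geometry, physiology and noise parameters of the phantom."""

    matrix: int = 200                 # image matrix (pixels, square)
    pixel_mm: float = 1.6             # in-plane pixel size
    n_slices: int = 12
    slice_thickness_mm: float = 8.0
    lv_edv_ml: float = 150.0
    lv_esv_ml: float = 54.0
    rv_edv_ml: float = 126.0
    rv_esv_ml: float = 53.0
    mean_rr_ms: float = 750.0
    rr_jitter_sd_ms: float = 25.0
    resp_period_s: float = 4.0
    resp_amp_mm: float = 10.0         # peak inspiratory displacement
    bellows_noise_sd_au: float = 60.0
    frame_rate: float = 30.0          # frames / s
    duration_s: float = 30.0          # acquisition time per slice
    blood_intensity: int = 800
    myo_intensity: int = 300
    background_intensity: int = 50
    noise_sd: float = 20.0            # pixel noise
    wall_mm: float = 8.0              # LV wall thickness
    rv_rim_mm: float = 4.8            # RV free-wall rim
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lv", "rv"):
            edv = getattr(self, f"{name}_edv_ml")
            esv = getattr(self, f"{name}_esv_ml")
            if not 0 < esv < edv:
                raise ValueError(f"{name}: need 0 < ESV < EDV, got {esv}, {edv}")
        if min(self.matrix, self.n_slices) <= 0 or self.pixel_mm <= 0:
            raise ValueError("dimensions must be positive")
        if self.frame_rate <= 0 or self.duration_s <= 0:
            raise ValueError("frame rate and duration must be positive")
        # geometric feasibility: largest LV disc + wall must fit its half-image
        a_max = self._max_slice_area_mm2(self.lv_edv_ml)
        r_px = np.sqrt(a_max / np.pi) / self.pixel_mm + self.wall_mm / self.pixel_mm
        if r_px > 0.2 * self.matrix:
            raise ValueError("ventricles exceed matrix: reduce volumes or pixel size")

    # -- geometry helpers ------------------------------------------------
    def slice_weights(self) -> np.ndarray:
        z = (np.arange(self.n_slices) + 0.5) / self.n_slices
        w = 1.0 - 0.8 * z**2
        return w / w.sum()

    def _max_slice_area_mm2(self, volume_ml: float) -> float:
        return float(volume_ml * 1000.0 / self.slice_thickness_mm * self.slice_weights().max())

    @property
    def lv_center_col(self) -> float:
        return 0.425 * self.matrix

    @property
    def rv_center_col(self) -> float:
        return 0.625 * self.matrix

    @property
    def heart_row(self) -> float:
        return 0.5 * self.matrix


@dataclass
class VentricleTruth:
    edv_ml: float
    esv_ml: float

    @property
    def sv_ml(self) -> float:
        return self.edv_ml - self.esv_ml

    @property
    def ef_pct(self) -> float:
        return 100.0 * self.sv_ml / self.edv_ml


@dataclass
class GroundTruth:
    """Analytic truth of one simulated acquisition."""

    lv: VentricleTruth
    rv: VentricleTruth
    config: PhantomConfig
    r_wave_times: np.ndarray = field(default=None, repr=False)

    def bellows_clean(self, t_ms) -> np.ndarray:
        """Noise-free bellows value (a.u.) at time t (ms since start)."""
        s = self.displacement_mm(t_ms)
        if self.config.resp_amp_mm == 0:
            return np.zeros_like(np.asarray(t_ms, dtype=float))
        return 4000.0 * s / self.config.resp_amp_mm

    def displacement_mm(self, t_ms) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float) / 1000.0
        return self.config.resp_amp_mm * (1.0 - np.cos(2.0 * np.pi * t / self.config.resp_period_s)) / 2.0

    def volume_ml(self, phase, ventricle: str = "lv") -> np.ndarray:
        """Blood-pool volume at cardiac phase in [0, 1)."""
        v = self.lv if ventricle == "lv" else self.rv
        return _volume_curve(np.asarray(phase, dtype=float), v.edv_ml, v.esv_ml)


def _volume_curve(phase: np.ndarray, edv: float, esv: float) -> np.ndarray:
    warped = (1.0 - np.cos(np.pi * phase)) / 2.0
    return esv + (edv - esv) * (1.0 + np.cos(2.0 * np.pi * warped)) / 2.0


def ground_truth_volumes(config: PhantomConfig) -> GroundTruth:
    """Analytic EDV/ESV/SV/EF per ventricle, without simulating frames."""
    return GroundTruth(
        lv=VentricleTruth(config.lv_edv_ml, config.lv_esv_ml),
        rv=VentricleTruth(config.rv_edv_ml, config.rv_esv_ml),
        config=config,
    )


def analysis_regions(config: PhantomConfig) -> dict:
    """Segmentation hints for phantom analysis: threshold and per-ventricle ROIs.

    The ROI boxes split the image at the inter-ventricular midline; a
    blood-pool component is attributed to the ventricle whose box holds
    its centroid.  The threshold sits midway between myocardium and
    blood so sub-pixel edge coverage is counted symmetrically.
    """
    m = config.matrix
    split = int(0.525 * m)
    return {
        "threshold": (config.myo_intensity + config.blood_intensity) / 2.0,
        "lv_roi": (slice(0, m), slice(int(0.15 * m), split)),
        "rv_roi": (slice(0, m), slice(split, int(0.9 * m))),
    }


def _draw_r_waves(config: PhantomConfig, rng: np.random.Generator, t_end_ms: float) -> np.ndarray:
    times = [0.0]
    floor = 0.6 * config.mean_rr_ms
    while times[-1] < t_end_ms + 2.0 * config.mean_rr_ms:
        gap = max(floor, rng.normal(config.mean_rr_ms, config.rr_jitter_sd_ms))
        times.append(round(times[-1] + gap, 3))
    return np.array(times)


def _ellipse_coverage(rows, cols, cy, cx, ry, rx):
    """Sub-pixel coverage of an axis-aligned ellipse on a pixel grid."""
    if ry <= 0 or rx <= 0:
        return np.zeros(np.broadcast_shapes(rows.shape, cols.shape))
    rho = np.sqrt(((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2)
    edge = min(rx, ry)
    return np.clip((1.0 - rho) * edge + 0.5, 0.0, 1.0)


def _render_frame(
    config: PhantomConfig,
    rows: np.ndarray,
    cols: np.ndarray,
    lv_area_mm2: float,
    rv_area_mm2: float,
    shift_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    px = config.pixel_mm
    cy = config.heart_row + shift_mm / px
    wall_px = config.wall_mm / px
    rim_px = config.rv_rim_mm / px

    r_lv = np.sqrt(max(lv_area_mm2, 0.0) / np.pi) / px
    a_rv = np.sqrt(max(rv_area_mm2, 0.0) / (0.6 * np.pi)) / px  # row semi-axis
    b_rv = 0.6 * a_rv

    lv_in = _ellipse_coverage(rows, cols, cy, config.lv_center_col, r_lv, r_lv)
    lv_out = _ellipse_coverage(rows, cols, cy, config.lv_center_col, r_lv + wall_px, r_lv + wall_px)
    rv_in = _ellipse_coverage(rows, cols, cy, config.rv_center_col, a_rv, b_rv)
    rv_out = _ellipse_coverage(rows, cols, cy, config.rv_center_col, a_rv + rim_px, b_rv + rim_px)

    cov_myo = np.maximum(lv_out, rv_out)
    cov_blood = np.maximum(lv_in, rv_in)
    img = (
        config.background_intensity
        + (config.myo_intensity - config.background_intensity) * cov_myo
        + (config.blood_intensity - config.myo_intensity) * cov_blood
    )
    img = img + rng.normal(0.0, config.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def simulate_acquisition(
    config: PhantomConfig,
) -> tuple[RTSeries, PhysioTrace, GroundTruth]:
    """Simulate one full slice-by-slice free-breathing acquisition.

    Returns the real-time series (bellows tags unset — assigning them is
    the pipeline's job), the noisy bellows trace, and the ground truth.
    Deterministic for a given config (``config.seed`` drives all noise).
    """
    rng = np.random.default_rng(config.seed)
    truth = ground_truth_volumes(config)
    total_ms = config.n_slices * config.duration_s * 1000.0
    r_waves = _draw_r_waves(config, rng, total_ms)
    truth.r_wave_times = r_waves

    weights = config.slice_weights()
    n_frames = int(round(config.frame_rate * config.duration_s))
    frame_period_ms = 1000.0 / config.frame_rate
    ax = np.arange(config.matrix, dtype=float)
    rows, cols = ax[:, None], ax[None, :]

    slices: list[list[RTFrame]] = []
    for si in range(config.n_slices):
        loc = round(si * config.slice_thickness_mm, 2)
        t_slice0 = si * config.duration_s * 1000.0
        frames = []
        for j in range(n_frames):
            t = round(t_slice0 + j * frame_period_ms, 3)
            k = int(np.searchsorted(r_waves, t, side="right")) - 1
            rr = r_waves[k + 1] - r_waves[k]
            trigger = round(t - r_waves[k], 3)
            phase = (t - r_waves[k]) / rr
            lv_vol = _volume_curve(np.array(phase), config.lv_edv_ml, config.lv_esv_ml)
            rv_vol = _volume_curve(np.array(phase), config.rv_edv_ml, config.rv_esv_ml)
            lv_area = float(lv_vol) * 1000.0 / config.slice_thickness_mm * weights[si]
            rv_area = float(rv_vol) * 1000.0 / config.slice_thickness_mm * weights[si]
            shift = float(truth.displacement_mm(t))
            pixels = _render_frame(config, rows, cols, lv_area, rv_area, shift, rng)
            frames.append(
                RTFrame(
                    pixels=pixels,
                    acq_time=t,
                    trigger_time=trigger,
                    slice_index=si,
                    slice_location=loc,
                    pixel_spacing=(config.pixel_mm, config.pixel_mm),
                    slice_thickness=config.slice_thickness_mm,
                )
            )
        slices.append(frames)

    # physio logging starts before and ends after the imaging window, so
    # filter edge transients never coincide with acquired frames
    margin_ms = 2000.0
    n_samp = int(round((total_ms + 2 * margin_ms) / 1000.0 * _PHYSIO_RATE_HZ)) + 1
    ts = np.round(np.arange(n_samp) * (1000.0 / _PHYSIO_RATE_HZ) - margin_ms, 3)
    clean = truth.bellows_clean(ts)
    noisy = clean + rng.normal(0.0, config.bellows_noise_sd_au, clean.shape)
    trace = PhysioTrace(ts, noisy)

    series = RTSeries(slices, frame_rate=config.frame_rate, duration=config.duration_s)
    series.validate()
    return series, trace, truth
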