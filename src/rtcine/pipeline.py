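"""End-to-end pipeline: simulate -> synchronize -> bin -> window -> volumetry.

`run_pipeline` ties the stages together under one configuration and
writes a machine-readable manifest (inputs, seed, per-bin logs, stage
timings, output checksums) next to the run artifacts.  Reruns with the
same configuration and seed produce byte-identical data files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

from . import dicom_io, physio, volumetry
from .binning import BinConfig, bin_series
from .phantom import PhantomConfig, analysis_regions, simulate_acquisition
from .windowing import apply_window, auto_window_type2

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Umbrella configuration for one pipeline run."""

    out_dir: str
    seed: int = 0
    # phantom (used when no input series is given)
    phantom: PhantomConfig | None = None
    # inputs (used instead of simulation when set)
    series_dir: str | None = None
    physio_file: str | None = None
    # physio preprocessing
    cutoff_hz: float = 1.0
    order: int = 4
    offset_ms: float = 0.0
    # binning
    mean_rr: float | None = None
    n_phases: int = 25
    gate_threshold: float = 2000.0
    median_target: float = 1000.0
    allow_fallback: bool = True
    # volumetry
    weight_kg: float | None = None
    height_cm: float | None = None
    write_previews: bool = False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return _T()

    truth = None
    if config.series_dir is not None:
        with stage("load"):
            series = dicom_io.read_rt_series(config.series_dir)
            if config.physio_file is None:
                raise ValueError("physio file required when loading a series")
            trace = dicom_io.read_physio_log(config.physio_file)
    else:
        with stage("simulate"):
            pconf = config.phantom or PhantomConfig(seed=config.seed)
            series, trace, truth = simulate_acquisition(pconf)
            dicom_io.write_rt_series(series, out / "rt_series")
            dicom_io.write_physio_log(trace, out / "physio.log")

    with stage("sync"):
        prepared = physio.preprocess_trace(trace, config.cutoff_hz, config.order)
        physio.assign_bellows_to_frames(prepared, series, config.offset_ms)

    with stage("bin"):
        mean_rr = config.mean_rr
        if mean_rr is None and truth is not None:
            mean_rr = truth.config.mean_rr_ms
        if mean_rr is None:
            from .binning import estimate_mean_rr

            mean_rr = estimate_mean_rr(series)
        bconf = BinConfig(
            mean_rr=mean_rr,
            n_phases=config.n_phases,
            gate_threshold=config.gate_threshold,
            median_target=config.median_target,
            allow_fallback=config.allow_fallback,
        )
        stack = bin_series(series, bconf)
        dicom_io.write_cine_stack(stack, out / "cine_stack")
        manifest["stages"]["bin"] = {
            "mean_rr": mean_rr,
            "phase_duration": stack.phase_duration,
            "n_fallback": int(sum(sum(f) for f in stack.fallback_flags)),
            "bins": [dataclasses.asdict(r) for r in stack.bin_results],
        }

    if config.write_previews:
        with stage("window"):
            from PIL import Image

            prev = out / "previews"
            prev.mkdir(exist_ok=True)
            for si, sl in enumerate(stack.frames):
                settings = auto_window_type2(sl[0].pixels)
                for k, f in enumerate(sl):
                    img = apply_window(f.pixels, settings)
                    Image.fromarray(img).save(prev / f"slice{si:02d}_phase{k:02d}.png")

    if truth is not None and config.weight_kg and config.height_cm:
        with stage("volumetry"):
            regions = analysis_regions(truth.config)
            bsa = volumetry.dubois_bsa(config.weight_kg, config.height_cm)
            report = {}
            for name in ("lv", "rv"):
                vols = volumetry.stack_phase_volumes(
                    stack, regions["threshold"], regions[f"{name}_roi"]
                )
                res = volumetry.ventricular_function(vols, bsa)
                report[name] = dataclasses.asdict(res)
            (out / "volumetry.json").write_text(json.dumps(report, indent=2))
            manifest["stages"]["volumetry"] = report

    manifest["timings"] = timings
    manifest["outputs"] = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
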