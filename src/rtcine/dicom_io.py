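"""DICOM and physio-log I/O for real-time frame series and binned cine stacks.

Single-frame DICOM files only.  The tags this module relies on:

* (0018,1060) Trigger Time — ms since the last ECG R wave (required on read)
* (0008,0032) Acquisition Time — converted to ms relative to the first frame
* (0020,1041) Slice Location — slice grouping key, rounded to 0.01 mm
* (0028,0030) Pixel Spacing, (0018,0050) Slice Thickness — geometry
* (0018,1090) Cardiac Number of Images — set to the phase count on cine output

Respiratory-bellows values travel in a private block (group 0x0019,
creator ``RTCINE``) with VR FD so floats round-trip exactly; binned
frames additionally carry a fallback flag there when the respiratory
gate had to be relaxed for their bin.

The physio log is plain text: two whitespace-separated columns
``timestamp_ms value``, header/comment lines prefixed with ``#``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

from .core import BinnedStack, PhysioTrace, RTFrame, RTSeries

__all__ = [
    "read_rt_series",
    "write_rt_series",
    "write_cine_stack",
    "read_physio_log",
    "write_physio_log",
]

_PRIVATE_CREATOR = "RTCINE"
_PRIVATE_GROUP = 0x0019
_BELLOWS_OFFSET = 0x01
_FALLBACK_OFFSET = 0x02


def _ms_to_tm(ms: float) -> str:
    """Milliseconds since series start -> DICOM TM string (µs resolution)."""
    total_us = round(ms * 1000.0)
    if total_us < 0:
        raise ValueError("negative acquisition time")
    s, us = divmod(total_us, 1_000_000)
    m, s = divmod(s, 60)
    h, m = divmod(m, 60)
    return f"{h:02d}{m:02d}{s:02d}.{us:06d}"


def _tm_to_ms(tm: str) -> float:
    tm = str(tm)
    h, m = int(tm[0:2]), int(tm[2:4])
    sec = tm[4:]
    if "." in sec:
        s_part, frac = sec.split(".")
        us = int(frac.ljust(6, "0")[:6])
    else:
        s_part, us = sec, 0
    total_us = ((h * 60 + m) * 60 + int(s_part)) * 1_000_000 + us
    return total_us / 1000.0


def _frame_dataset(frame: RTFrame, uids: dict, instance_number: int) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = MRImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(
        entropy_srcs=[uids["series"], f"inst{instance_number}"]
    )
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = MRImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = uids["study"]
    ds.SeriesInstanceUID = uids["series"]
    ds.Modality = "MR"
    ds.PatientName = "PHANTOM^RTCINE"
    ds.PatientID = "RTCINE"
    ds.StudyDate = "20220101"
    ds.ContentDate = "20220101"
    ds.StudyTime = "000000"
    ds.InstanceNumber = instance_number
    ds.SliceLocation = f"{round(frame.slice_location, 2)}"
    ds.SliceThickness = f"{frame.slice_thickness}"
    ds.PixelSpacing = [f"{frame.pixel_spacing[0]}", f"{frame.pixel_spacing[1]}"]
    ds.TriggerTime = f"{frame.trigger_time}"
    ds.AcquisitionTime = _ms_to_tm(frame.acq_time)

    px = np.ascontiguousarray(frame.pixels)
    if px.dtype != np.uint16:
        if px.min() < 0 or px.max() > 0xFFFF:
            raise ValueError("pixel values outside uint16 range")
        px = px.astype(np.uint16)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = px.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = px.tobytes()

    if frame.bellows is not None:
        block = ds.private_block(_PRIVATE_GROUP, _PRIVATE_CREATOR, create=True)
        block.add_new(_BELLOWS_OFFSET, "FD", float(frame.bellows))
    return ds


def _frame_from_dataset(ds: Dataset, path: str) -> tuple[RTFrame, int]:
    if "TriggerTime" not in ds:
        raise ValueError(f"missing Trigger Time (0018,1060) in {path}")
    bellows = None
    try:
        block = ds.private_block(_PRIVATE_GROUP, _PRIVATE_CREATOR)
        if block and (_PRIVATE_GROUP, block.block_start | _BELLOWS_OFFSET) in ds:
            bellows = float(block[_BELLOWS_OFFSET].value)
    except KeyError:
        pass
    frame = RTFrame(
        pixels=ds.pixel_array,
        acq_time=_tm_to_ms(ds.AcquisitionTime) if "AcquisitionTime" in ds else 0.0,
        trigger_time=float(ds.TriggerTime),
        slice_location=float(ds.get("SliceLocation", 0.0)),
        pixel_spacing=tuple(float(v) for v in ds.get("PixelSpacing", [1.0, 1.0])),
        slice_thickness=float(ds.get("SliceThickness", 8.0)),
        bellows=bellows,
    )
    return frame, int(ds.get("InstanceNumber", 0))


def _series_entropy(frames: list[RTFrame]) -> str:
    """Deterministic UID entropy from series content (not from paths),
    so identical data written anywhere yields identical files."""
    h = hashlib.sha256()
    for f in frames:
        h.update(f"{f.acq_time}|{f.trigger_time}|{f.slice_location}".encode())
        h.update(f.pixels.tobytes()[:64])
    return h.hexdigest()


def _collect_dicom_paths(path) -> list[Path]:
    if isinstance(path, (list, tuple)):
        return [Path(f) for f in path]
    p = Path(path)
    if p.is_dir():
        return [f for f in p.iterdir() if f.is_file() and f.suffix.lower() == ".dcm"]
    raise ValueError(f"not a directory or file list: {path}")


def read_rt_series(path, frame_rate: float = 30.0, duration: float = 30.0) -> RTSeries:
    """Read a directory (or explicit list) of single-frame DICOM files.

    Frames are grouped by Slice Location (rounded to 0.01 mm, ascending)
    and sorted within each slice by acquisition time, ties broken by
    Instance Number, so the result is independent of filesystem listing
    order.  Acquisition times are rebased to ms since the earliest frame.

    Raises ``ValueError`` if no frames are found, any frame lacks
    Trigger Time, or matrix sizes are inconsistent.
    """
    files = _collect_dicom_paths(path)
    if not files:
        raise ValueError(f"no DICOM frames found in {path}")
    records = []
    for f in sorted(files):
        ds = pydicom.dcmread(f)
        frame, inst = _frame_from_dataset(ds, str(f))
        records.append((round(frame.slice_location, 2), frame.acq_time, inst, frame))
    shapes = {r[3].pixels.shape for r in records}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent matrix sizes across series: {sorted(shapes)}")
    t0 = min(r[1] for r in records)
    slices: dict[float, list] = {}
    for loc, t, inst, frame in records:
        frame.acq_time = t - t0
        slices.setdefault(loc, []).append((frame.acq_time, inst, frame))
    frames = []
    for idx, loc in enumerate(sorted(slices)):
        group = sorted(slices[loc], key=lambda r: (r[0], r[1]))
        for _, _, fr in group:
            fr.slice_index = idx
        frames.append([fr for _, _, fr in group])
    series = RTSeries(frames=frames, frame_rate=frame_rate, duration=duration)
    series.validate()
    return series


def write_rt_series(series: RTSeries, path) -> list[Path]:
    """Write one DICOM file per frame; returns the written paths."""
    series.validate()
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    ent = _series_entropy(series.all_frames())
    uids = {
        "study": generate_uid(entropy_srcs=["rtcine-study", ent]),
        "series": generate_uid(entropy_srcs=["rtcine-rt-series", ent]),
    }
    written = []
    instance = 1
    for si, sl in enumerate(series.frames):
        for fi, frame in enumerate(sl):
            ds = _frame_dataset(frame, uids, instance)
            fname = out / f"slice{si:02d}_frame{fi:04d}.dcm"
            ds.save_as(fname, enforce_file_format=True)
            written.append(fname)
            instance += 1
    return written


def write_cine_stack(stack: BinnedStack, path) -> list[Path]:
    """Write a binned stack as a cine DICOM series (one file per phase per slice).

    Each file carries Cardiac Number of Images = ``n_phases`` and a
    Trigger Time at the midpoint of its phase bin, ``(k + 0.5) * w``, so
    standard cine viewers order the phases correctly.  Frames whose bin
    needed the respiratory-gate fallback carry a private flag.
    """
    stack.validate()
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    n = stack.n_phases
    w = stack.phase_duration
    ent = _series_entropy([f for sl in stack.frames for f in sl])
    uids = {
        "study": generate_uid(entropy_srcs=["rtcine-study", ent]),
        "series": generate_uid(entropy_srcs=["rtcine-cine-series", ent]),
    }
    written = []
    instance = 1
    for si, sl in enumerate(stack.frames):
        for k, frame in enumerate(sl):
            f2 = RTFrame(
                pixels=frame.pixels,
                acq_time=frame.acq_time,
                trigger_time=round((k + 0.5) * w, 3),
                slice_index=si,
                slice_location=frame.slice_location,
                pixel_spacing=frame.pixel_spacing,
                slice_thickness=frame.slice_thickness,
                bellows=frame.bellows,
            )
            ds = _frame_dataset(f2, uids, instance)
            ds.CardiacNumberOfImages = n
            if stack.fallback_flags[si][k]:
                block = ds.private_block(_PRIVATE_GROUP, _PRIVATE_CREATOR, create=True)
                block.add_new(_FALLBACK_OFFSET, "US", 1)
            fname = out / f"slice{si:02d}_phase{k:02d}.dcm"
            ds.save_as(fname, enforce_file_format=True)
            written.append(fname)
            instance += 1
    return written


def read_physio_log(path) -> PhysioTrace:
    """Parse a two-column ``timestamp_ms value`` text log (``#`` comments)."""
    ts, vals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            ts.append(float(parts[0]))
            vals.append(float(parts[1]))
    if not ts:
        raise ValueError(f"empty physio log: {path}")
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"non-monotone timestamps in physio log: {path}")
    return PhysioTrace(np.array(ts), np.array(vals))


def write_physio_log(trace: PhysioTrace, path) -> None:
    """Write a trace in the two-column dialect; values at full float precision."""
    with open(path, "w") as fh:
        fh.write("# rtcine physio log\n# timestamp_ms value\n")
        for t, v in zip(trace.timestamps, trace.values):
            fh.write(f"{float(t)!r} {float(v)!r}\n")
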