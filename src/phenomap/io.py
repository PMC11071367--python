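"""Readers and writers for the pipeline's on-disk formats.

CSV is the first-class interchange format for traces (``time,eeg,emg`` and
``time,iso,da,ach``); EDF reading is available when ``mne`` is installed.
Section images travel as grayscale TIFF, tables as CSV, and summaries /
truth objects as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .histoquant import SectionImage
from .photometry import PhotometrySession
from .sleepsig import EpochGrid, PolysomnogramRecord


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable,
                                     allow_nan=True))


def read_json(path):
    return json.loads(Path(path).read_text())


# --- polysomnograms ---------------------------------------------------------

def write_polysomnogram_csv(rec: PolysomnogramRecord, path) -> None:
    t = rec.start_time + np.arange(rec.eeg.size) / rec.rate_hz
    pd.DataFrame({"time": t, "eeg": rec.eeg, "emg": rec.emg}).to_csv(path, index=False)


def read_polysomnogram_csv(path, rate_hz: float | None = None, **labels) -> PolysomnogramRecord:
    df = pd.read_csv(path)
    for col in ("time", "eeg", "emg"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    t = df["time"].to_numpy()
    if rate_hz is None:
        if len(t) < 2:
            raise ValueError("cannot infer rate from a single sample")
        rate_hz = round(1.0 / float(np.median(np.diff(t))), 6)
    return PolysomnogramRecord(
        eeg=df["eeg"].to_numpy(), emg=df["emg"].to_numpy(),
        rate_hz=float(rate_hz), start_time=float(t[0]), **labels)


def read_polysomnogram_edf(path, eeg_channel: str, emg_channel: str, **labels) -> PolysomnogramRecord:
    """Read EEG/EMG channels (by name) from an EDF file.  Requires ``mne``."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("EDF input requires the 'mne' package (pip install phenomap[edf])") from e
    raw = mne.io.read_raw_edf(path, include=[eeg_channel, emg_channel],
                              preload=True, verbose="error")
    return PolysomnogramRecord(
        eeg=raw.get_data(picks=eeg_channel)[0],
        emg=raw.get_data(picks=emg_channel)[0],
        rate_hz=float(raw.info["sfreq"]),
        **labels,
    )


# --- epoch grids ------------------------------------------------------------

def write_epoch_grid_csv(grid: EpochGrid, path) -> None:
    df = grid.frame.copy()
    df.attrs = {}
    df.to_csv(path, index=False)


def read_epoch_grid_csv(path, epoch_s: float = 20.0, rate_hz: float = 500.0) -> EpochGrid:
    frame = pd.read_csv(path)
    frame["stage"] = frame["stage"].astype(str)
    frame["artifact"] = frame["artifact"].astype(bool)
    frame["rbd"] = frame["rbd"].astype(bool)
    return EpochGrid(frame, epoch_s=epoch_s, rate_hz=rate_hz)


# --- photometry -------------------------------------------------------------

def write_photometry_csv(session: PhotometrySession, path) -> None:
    t = session.start_time + np.arange(session.n_samples) / session.rate_hz
    pd.DataFrame({"time": t, **session.channels}).to_csv(path, index=False)


def read_photometry_csv(path, rate_hz: float | None = None, **labels) -> PhotometrySession:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"missing 'time' column in {path}")
    t = df["time"].to_numpy()
    if rate_hz is None:
        if len(t) < 2:
            raise ValueError("cannot infer rate from a single sample")
        rate_hz = round(1.0 / float(np.median(np.diff(t))), 6)
    channels = {c: df[c].to_numpy() for c in df.columns if c != "time"}
    return PhotometrySession(channels=channels, rate_hz=float(rate_hz),
                             start_time=float(t[0]), **labels)


# --- images -----------------------------------------------------------------

def write_section_tiff(img: SectionImage, path, dtype=np.uint8) -> None:
    data = np.clip(img.data, 0, np.iinfo(dtype).max).astype(dtype)
    tifffile.imwrite(path, data)


def read_section_tiff(path, pixel_size_um: float = 6.25,
                      pixel_area_um2: float = 6.25,
                      polarity: str = "light-on-dark") -> SectionImage:
    return SectionImage(
        data=tifffile.imread(path).astype(float),
        pixel_size_um=pixel_size_um,
        pixel_area_um2=pixel_area_um2,
        polarity=polarity,
    )
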