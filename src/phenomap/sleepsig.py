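"""Epoch-based sleep staging and RBD detection from EEG/EMG.

The pipeline follows the telemetry-analysis conventions of rodent
polysomnography: recordings are cut into fixed 20 s epochs ("the signal
grid"), each epoch gets an EMG root-mean-square value and a Welch relative
band-power profile of the EEG (1024-sample Hamming segments, 50% overlap,
0.3-80 Hz total band), stages are assigned from three equally weighted
z-scored features (delta%, theta%/delta%, EMG RMS), and REM epochs whose EMG
RMS exceeds the REM-baseline mean by more than two standard deviations are
flagged as RBD (loss of atonia) and merged into contiguous events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig

WAKE, NREM, REM, UNSCORED = "WAKE", "NREM", "REM", "UNSCORED"
STAGES = (WAKE, NREM, REM)

#: EEG band windows in Hz.  Half-open [lo, hi) except high_gamma, which is
#: closed at 80 Hz; 0.3-0.5 and 49-51 Hz (line-noise notch) are deliberately
#: not covered, so the seven bands sum to < 100%.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 24.0),
    "low_gamma": (24.0, 49.0),
    "high_gamma": (51.0, 80.0),
}
TOTAL_BAND = (0.3, 80.0)
BAND_NAMES = tuple(BANDS)

WELCH_NPERSEG = 1024  # 2**10 samples per Hamming segment
WELCH_OVERLAP = 0.5


@dataclass
class PolysomnogramRecord:
    """Raw EEG/EMG (same rate) plus optional 1 Hz activity and labels."""

    eeg: np.ndarray
    emg: np.ndarray
    rate_hz: float
    activity: np.ndarray | None = None
    start_time: float = 0.0
    animal_id: str = ""
    group: str = ""
    sex: str = ""

    def __post_init__(self):
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape:
            raise ValueError("eeg and emg must have the same length")
        if self.eeg.size == 0:
            raise ValueError("zero-length recording")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")


@dataclass
class EpochGrid:
    """Per-epoch signal grid: timestamps, EMG RMS, band powers, stage, flags."""

    frame: pd.DataFrame
    epoch_s: float
    rate_hz: float
    animal_id: str = ""
    excluded: bool = False
    exclusion_reason: str | None = None

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def stage(self) -> np.ndarray:
        return self.frame["stage"].to_numpy()

    @property
    def emg_rms(self) -> np.ndarray:
        return self.frame["emg_rms"].to_numpy()

    @property
    def rbd(self) -> np.ndarray:
        return self.frame["rbd"].to_numpy()

    def copy(self) -> "EpochGrid":
        return EpochGrid(self.frame.copy(), self.epoch_s, self.rate_hz,
                         self.animal_id, self.excluded, self.exclusion_reason)


@dataclass
class RBDEvent:
    """Maximal run of contiguous RBD-flagged REM epochs."""

    start_epoch: int
    end_epoch: int  # inclusive
    n_epochs: int
    peak_emg_rms: float
    threshold: float


@dataclass
class SleepSummary:
    pct_time: dict[str, float]
    event_counts: dict[str, int]
    mean_event_duration_s: dict[str, float]
    longest_event_duration_s: dict[str, float]
    n_rbd_events: int
    rbd_per_rem_pct: float | None
    excluded: bool = False
    exclusion_reason: str | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pct_time": self.pct_time,
            "event_counts": self.event_counts,
            "mean_event_duration_s": self.mean_event_duration_s,
            "longest_event_duration_s": self.longest_event_duration_s,
            "n_rbd_events": self.n_rbd_events,
            "rbd_per_rem_pct": self.rbd_per_rem_pct,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            **({"extras": self.extras} if self.extras else {}),
        }


def _band_mask(freqs: np.ndarray, name: str) -> np.ndarray:
    lo, hi = BANDS[name]
    if name == "high_gamma":
        return (freqs >= lo) & (freqs <= hi)
    return (freqs >= lo) & (freqs < hi)


def _welch_psd(x: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    return spsig.welch(
        x,
        fs=rate_hz,
        window="hamming",
        nperseg=WELCH_NPERSEG,
        noverlap=int(WELCH_NPERSEG * WELCH_OVERLAP),
        detrend="constant",
        axis=-1,
    )


def epoch_band_powers(eeg_epoch: np.ndarray, rate_hz: float) -> dict[str, float]:
    """Relative band powers (% of total 0.3-80 Hz power) for one EEG epoch.

    Welch average of Hamming-windowed 1024-sample modified periodograms with
    50% overlap; the partial trailing segment is dropped.
    """
    x = np.asarray(eeg_epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D epoch")
    if x.size < WELCH_NPERSEG:
        raise ValueError(f"epoch shorter than one {WELCH_NPERSEG}-sample segment")
    freqs, psd = _welch_psd(x, rate_hz)
    total_mask = (freqs >= TOTAL_BAND[0]) & (freqs <= TOTAL_BAND[1])
    total = float(psd[total_mask].sum())
    if not np.isfinite(total) or total <= 0.0:
        raise ValueError("zero total power in 0.3-80 Hz")
    return {
        name: float(100.0 * psd[_band_mask(freqs, name)].sum() / total)
        for name in BAND_NAMES
    }


def _band_power_matrix(epochs: np.ndarray, rate_hz: float) -> np.ndarray:
    """Vectorised relative band powers, one row per epoch; NaN rows where the
    total power is degenerate or the epoch contains non-finite samples."""
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs, psd = _welch_psd(epochs, rate_hz)
        total_mask = (freqs >= TOTAL_BAND[0]) & (freqs <= TOTAL_BAND[1])
        total = psd[:, total_mask].sum(axis=1)
        out = np.full((epochs.shape[0], len(BAND_NAMES)), np.nan)
        ok = np.isfinite(total) & (total > 0.0)
        for j, name in enumerate(BAND_NAMES):
            out[ok, j] = 100.0 * psd[np.ix_(ok, _band_mask(freqs, name))].sum(axis=1) / total[ok]
    return out


def _rail_artifact_samples(x: np.ndarray, rail: float, min_run: int) -> np.ndarray:
    """Samples belonging to runs of >= min_run consecutive values pinned at
    +/-rail (digitizer saturation)."""
    hit = (x == rail) | (x == -rail)
    if not hit.any():
        return np.zeros_like(hit)
    h = hit.astype(np.int8)
    edges = np.flatnonzero(np.diff(h))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges, len(h) - 1]
    bad = np.zeros_like(hit)
    for s, e in zip(starts, ends):
        if h[s] and (e - s + 1) >= min_run:
            bad[s : e + 1] = True
    return bad


def build_signal_grid(
    rec: PolysomnogramRecord,
    epoch_s: float = 20.0,
    rail: float | None = None,
) -> EpochGrid:
    """Cut a recording into epochs and compute the per-epoch signal grid.

    EMG RMS is sqrt(mean(emg**2)) within the epoch; band powers come from
    :func:`epoch_band_powers`.  Epochs containing non-finite samples or
    sustained rail-pinned samples (exact repetition of +/-rail for at least
    rate_hz/10 samples; rail defaults to the recording's max absolute value)
    are flagged as artifacts.  The trailing partial epoch is dropped.
    """
    spp_f = rec.rate_hz * epoch_s
    spp = int(round(spp_f))
    if abs(spp_f - spp) > 1e-9 or spp <= 0:
        raise ValueError("rate_hz * epoch_s must be an integer number of samples")
    n_epochs = rec.eeg.size // spp
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")

    eeg = rec.eeg[: n_epochs * spp].reshape(n_epochs, spp)
    emg = rec.emg[: n_epochs * spp].reshape(n_epochs, spp)

    with np.errstate(invalid="ignore"):
        emg_rms = np.sqrt(np.mean(emg**2, axis=1))

    artifact = ~(np.isfinite(eeg).all(axis=1) & np.isfinite(emg).all(axis=1))
    min_run = max(2, int(round(rec.rate_hz / 10.0)))
    for x in (rec.eeg, rec.emg):
        finite = x[np.isfinite(x)]
        railval = rail if rail is not None else (float(np.max(np.abs(finite))) if finite.size else 0.0)
        if railval > 0:
            bad = _rail_artifact_samples(x[: n_epochs * spp], railval, min_run)
            artifact |= bad.reshape(n_epochs, spp).any(axis=1)

    bands = _band_power_matrix(eeg, rec.rate_hz)
    artifact |= ~np.isfinite(bands).all(axis=1)

    frame = pd.DataFrame({"time_s": rec.start_time + epoch_s * np.arange(n_epochs)})
    frame["emg_rms"] = emg_rms
    for j, name in enumerate(BAND_NAMES):
        frame[name] = bands[:, j]
    frame["stage"] = UNSCORED
    frame["artifact"] = artifact
    frame["rbd"] = False
    return EpochGrid(frame, epoch_s, rec.rate_hz, animal_id=rec.animal_id)


def score_stages(grid: EpochGrid, max_artifact_fraction: float = 0.01) -> EpochGrid:
    """Assign WAKE/NREM/REM from three equally weighted z-scored features.

    Features: z(delta%), z(theta%/delta%), z(EMG RMS), standardised over
    non-artifact epochs.  Composite scores
    S_WAKE = z_emg, S_NREM = z_delta - z_emg, S_REM = z_td - z_emg; the stage
    is the argmax (ties resolve to WAKE).  Artifact epochs stay UNSCORED; a
    grid whose artifact fraction exceeds ``max_artifact_fraction`` (default
    1%) is marked excluded.
    """
    out = grid.copy()
    f = out.frame
    delta = f["delta"].to_numpy()
    theta = f["theta"].to_numpy()
    emg_rms = f["emg_rms"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        td = np.where(delta > 0, theta / delta, np.nan)
    valid = (~f["artifact"].to_numpy()) & np.isfinite(delta) & np.isfinite(td) & np.isfinite(emg_rms)
    if valid.sum() < 10:
        raise ValueError("fewer than 10 scorable epochs")

    feats = np.column_stack([delta, td, emg_rms])
    mu = feats[valid].mean(axis=0)
    sd = feats[valid].std(axis=0)
    if np.any(sd == 0.0):
        raise ValueError("degenerate recording: zero variance in a staging feature")
    z = (feats - mu) / sd
    z_delta, z_td, z_emg = z.T
    scores = np.column_stack([z_emg, z_delta - z_emg, z_td - z_emg])
    labels = np.array(STAGES)[np.argmax(scores, axis=1)]
    stage = np.where(valid, labels, UNSCORED)
    f["stage"] = stage

    art_frac = float(f["artifact"].mean())
    if art_frac > max_artifact_fraction:
        out.excluded = True
        out.exclusion_reason = (
            f"artifact fraction {100 * art_frac:.2f}% exceeds "
            f"{100 * max_artifact_fraction:.0f}%"
        )
    return out


def _contiguous_runs(indices: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs (start, end inclusive) of consecutive integers."""
    if indices.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > 1)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, indices.size - 1]
    return [(int(indices[s]), int(indices[e])) for s, e in zip(starts, ends)]


def rem_run_count(grid: EpochGrid) -> int:
    """Number of maximal contiguous REM runs (the 'REM events' denominator)."""
    return len(_contiguous_runs(np.flatnonzero(grid.stage == REM)))


def rbd_threshold(
    rem_rms: np.ndarray, mode: str = "mean2sd", k: float = 2.0, max_iter: int = 20
) -> float:
    """EMG-RMS atonia-loss threshold over a recording's REM epochs.

    ``mean2sd`` (default): mean + k*SD in a single pass over all REM epochs.
    ``robust``: median + k * 1.4826*MAD.
    ``iterative``: mean + k*SD recomputed excluding flagged epochs until stable.
    """
    x = np.asarray(rem_rms, dtype=float)
    if x.size == 0:
        raise ValueError("no REM epochs")
    if mode == "mean2sd":
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        return float(x.mean() + k * sd)
    if mode == "robust":
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        return med + k * 1.4826 * mad
    if mode == "iterative":
        keep = np.ones(x.size, dtype=bool)
        thr = float("inf")
        for _ in range(max_iter):
            base = x[keep]
            sd = float(np.std(base, ddof=1)) if base.size > 1 else 0.0
            thr = float(base.mean() + k * sd)
            keep_new = ~(x > thr)
            if np.array_equal(keep_new, keep):
                break
            keep = keep_new
        return thr
    raise ValueError(f"unknown baseline mode {mode!r}")


def detect_rbd_events(
    grid: EpochGrid, mode: str = "mean2sd", k: float = 2.0
) -> tuple[EpochGrid, list[RBDEvent]]:
    """Flag REM epochs with EMG RMS strictly above the REM baseline threshold
    and merge contiguous flagged epochs into RBD events."""
    out = grid.copy()
    f = out.frame
    rem_idx = np.flatnonzero(out.stage == REM)
    f["rbd"] = False
    if rem_idx.size == 0:
        return out, []
    if rem_idx.size < 3:
        warnings.warn("fewer than 3 REM epochs: RBD threshold is poorly determined")
    rms = out.emg_rms[rem_idx]
    thr = rbd_threshold(rms, mode=mode, k=k)
    flagged = rem_idx[rms > thr]
    col = f.columns.get_loc("rbd")
    f.iloc[flagged, col] = True
    events = [
        RBDEvent(
            start_epoch=s,
            end_epoch=e,
            n_epochs=e - s + 1,
            peak_emg_rms=float(out.emg_rms[s : e + 1].max()),
            threshold=thr,
        )
        for s, e in _contiguous_runs(flagged)
    ]
    return out, events


def summarize_sleep(
    grid: EpochGrid,
    events: list[RBDEvent] | None = None,
    interval_s: tuple[float, float] | None = None,
) -> SleepSummary:
    """Sleep-architecture summary: % time per stage over scored epochs, stage
    event counts and durations (maximal runs of identical labels), and RBD
    metrics.  ``interval_s`` optionally restricts the summary to a time window
    (e.g. light or dark phase)."""
    f = grid.frame
    if interval_s is not None:
        t0, t1 = interval_s
        f = f[(f["time_s"] >= t0) & (f["time_s"] < t1)]
    stage = f["stage"].to_numpy()
    scored = np.isin(stage, STAGES)
    n_scored = int(scored.sum())
    if n_scored == 0:
        raise ValueError("no scored epochs to summarize")
    pct = {s: float(100.0 * np.sum(stage == s) / n_scored) for s in STAGES}

    counts: dict[str, int] = {s: 0 for s in STAGES}
    durs: dict[str, list[int]] = {s: [] for s in STAGES}
    i = 0
    while i < len(stage):
        j = i
        while j + 1 < len(stage) and stage[j + 1] == stage[i]:
            j += 1
        if stage[i] in counts:
            counts[stage[i]] += 1
            durs[stage[i]].append(j - i + 1)
        i = j + 1

    mean_dur = {
        s: (float(np.mean(durs[s]) * grid.epoch_s) if durs[s] else float("nan"))
        for s in STAGES
    }
    longest = {
        s: (float(np.max(durs[s]) * grid.epoch_s) if durs[s] else float("nan"))
        for s in STAGES
    }
    n_rbd = len(events) if events is not None else 0
    n_rem_runs = counts[REM]
    rbd_pct = 100.0 * n_rbd / n_rem_runs if n_rem_runs > 0 else None
    return SleepSummary(
        pct_time=pct,
        event_counts=counts,
        mean_event_duration_s=mean_dur,
        longest_event_duration_s=longest,
        n_rbd_events=n_rbd,
        rbd_per_rem_pct=rbd_pct,
        excluded=grid.excluded,
        exclusion_reason=grid.exclusion_reason,
    )
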