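"""Fiber-photometry preprocessing and alignment to sleep epochs.

Traces (isosbestic control plus sensor channels, e.g. dopamine and
acetylcholine indicators) are block-averaged down to 500 Hz, z-scored within
consecutive non-overlapping 60 s windows, averaged within each 20 s scoring
epoch, and aggregated by behavioural state with RBD kept distinct from plain
REM.  Paired comparisons between states (e.g. REM vs RBD dopamine) use a
two-sided paired t-test across animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sleepsig import EpochGrid, STAGES
from .stats import TestResult, t_test

__all__ = [
    "PhotometrySession",
    "StateAlignedSignal",
    "preprocess_trace",
    "align_to_epochs",
    "compare_states",
]

PHOTOMETRY_STATES = (*STAGES, "RBD")


@dataclass
class PhotometrySession:
    """Named traces sharing one rate and the polysomnogram clock."""

    channels: dict[str, np.ndarray]
    rate_hz: float
    start_time: float = 0.0
    animal_id: str = ""
    degenerate_windows: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {v.size for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have the same length")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size if self.channels else 0


@dataclass
class StateAlignedSignal:
    """Per-epoch channel means plus per-state aggregates for one animal."""

    per_epoch: pd.DataFrame  # columns: epoch, state, one column per channel
    state_means: dict[str, dict[str, float]]  # channel -> state -> mean
    state_n: dict[str, int]  # state -> n epochs
    animal_id: str = ""


def preprocess_trace(
    session: PhotometrySession,
    target_hz: float = 500.0,
    zwin_s: float = 60.0,
    zscore: bool = True,
) -> PhotometrySession:
    """Downsample by block averaging and z-score in fixed 60 s windows.

    The raw rate must be an integer multiple of ``target_hz``; a 500 Hz input
    passes through the downsampler unchanged.  Windows are non-overlapping
    and aligned to the trace start; the trailing partial window is z-scored
    on its own samples.  Windows with SD < 1e-12 emit zeros and are recorded
    in ``degenerate_windows``.  ``zscore=False`` skips normalization (useful
    for piecewise-constant test signals).
    """
    ratio_f = session.rate_hz / target_hz
    ratio = int(round(ratio_f))
    if abs(ratio_f - ratio) > 1e-9 or ratio < 1:
        raise ValueError("raw rate must be an integer multiple of target_hz")
    if session.n_samples == 0:
        raise ValueError("empty trace")

    degenerate: list[tuple[str, int]] = []
    out: dict[str, np.ndarray] = {}
    win = int(round(zwin_s * target_hz))
    for name, x in session.channels.items():
        n = (x.size // ratio) * ratio
        y = x[:n].reshape(-1, ratio).mean(axis=1) if ratio > 1 else x.copy()
        if zscore:
            if y.size < 1:
                raise ValueError("trace shorter than one sample after downsampling")
            z = np.empty_like(y)
            for w, s0 in enumerate(range(0, y.size, win)):
                seg = y[s0 : s0 + win]
                sd = seg.std()
                if sd < 1e-12:
                    z[s0 : s0 + win] = 0.0
                    degenerate.append((name, w))
                else:
                    z[s0 : s0 + win] = (seg - seg.mean()) / sd
            y = z
        out[name] = y
    return PhotometrySession(
        channels=out,
        rate_hz=target_hz,
        start_time=session.start_time,
        animal_id=session.animal_id,
        degenerate_windows=degenerate,
    )


def align_to_epochs(session: PhotometrySession, grid: EpochGrid) -> StateAlignedSignal:
    """Average each channel within every [t, t+20 s) scoring epoch and
    aggregate by state; an epoch's state is RBD when its RBD flag is set,
    otherwise its stage."""
    spe = int(round(grid.epoch_s * session.rate_hz))
    n_full = session.n_samples // spe
    offset = int(round((grid.frame["time_s"].iloc[0] - session.start_time) * session.rate_hz))
    if offset != 0:
        raise ValueError("session and grid must share a time origin")
    n_epochs = min(n_full, len(grid))
    if n_epochs < 1:
        raise ValueError("no temporal overlap between trace and epoch grid")

    states = np.where(grid.rbd[:n_epochs], "RBD", grid.stage[:n_epochs])
    data = {"epoch": np.arange(n_epochs), "state": states}
    for name, x in session.channels.items():
        data[name] = x[: n_epochs * spe].reshape(n_epochs, spe).mean(axis=1)
    per_epoch = pd.DataFrame(data)

    state_means: dict[str, dict[str, float]] = {name: {} for name in session.channels}
    state_n: dict[str, int] = {}
    for state in PHOTOMETRY_STATES:
        sel = per_epoch["state"] == state
        state_n[state] = int(sel.sum())
        for name in session.channels:
            if state_n[state]:
                state_means[name][state] = float(per_epoch.loc[sel, name].mean())
    return StateAlignedSignal(per_epoch, state_means, state_n, session.animal_id)


def compare_states(
    per_animal: list[StateAlignedSignal],
    state_a: str,
    state_b: str,
    channel: str,
) -> TestResult:
    """Paired two-sided t-test on per-animal (state_a - state_b) aggregates.

    Animals missing either state are dropped and counted in
    ``extras['n_dropped']``.
    """
    a_vals, b_vals = [], []
    dropped = 0
    for sig in per_animal:
        means = sig.state_means.get(channel)
        if means is None:
            raise ValueError(f"channel {channel!r} missing from aligned signal")
        if state_a in means and state_b in means:
            a_vals.append(means[state_a])
            b_vals.append(means[state_b])
        else:
            dropped += 1
    if len(a_vals) < 2:
        raise ValueError("need at least 2 animals with both states")
    res = t_test(a_vals, b_vals, paired=True)
    res.extras["n_pairs"] = len(a_vals)
    res.extras["n_dropped"] = dropped
    res.extras["states"] = (state_a, state_b)
    res.extras["channel"] = channel
    return res
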