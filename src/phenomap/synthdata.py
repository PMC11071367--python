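"""Synthetic polysomnograms, photometry sessions, and histology images.

Every generator is a pure function of (config, seed) and returns the ground
truth alongside the data, so each downstream stage of the pipeline can be
validated without any recorded data.  The generators emulate the *structure*
of the real modalities (stage-dependent EEG spectra and EMG tone, phasic REM
bursts, state-dependent photometry offsets, elliptical stain clusters on
textured tissue, group series with localized intensity effects), not their
full physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as spsig
from scipy.ndimage import gaussian_filter
from skimage import draw as skdraw

from .sleepsig import NREM, REM, STAGES, WAKE, PolysomnogramRecord
from .histoquant import SectionImage, classify_area

__all__ = [
    "SynthSleepConfig",
    "StageTruth",
    "SynthPhotometryConfig",
    "SynthImageConfig",
    "DiskSpec",
    "DumbbellSpec",
    "SynthGroupSeriesConfig",
    "generate_stage_sequence",
    "generate_polysomnogram",
    "generate_photometry",
    "generate_section_image",
    "random_disk_specs",
    "generate_group_sections",
]

#: Default per-epoch Markov transition matrix over (WAKE, NREM, REM); the
#: stationary distribution is ~50/40/10% with mean REM runs of 5 epochs,
#: a mouse-like 24 h architecture.
DEFAULT_TRANSITIONS = np.array(
    [
        [0.92, 0.08, 0.00],
        [0.05, 0.90, 0.05],
        [0.20, 0.00, 0.80],
    ]
)

DEFAULT_BAND_AMPLITUDES = {
    WAKE: {"delta": 0.5, "theta": 1.0, "broad": 1.0},
    NREM: {"delta": 3.0, "theta": 0.5, "broad": 1.0},
    REM: {"delta": 0.3, "theta": 2.5, "broad": 1.0},
}

DEFAULT_EMG_TONE = {WAKE: 1.0, NREM: 0.4, REM: 0.1}

DELTA_HZ = 1.5
THETA_HZ = 6.5

# pink (1/f-ish) noise shaping filter (Paul Kellet's economy coefficients)
_PINK_B = [0.049922035, -0.095993537, 0.050612699, -0.004408786]
_PINK_A = [1.0, -2.494956002, 2.017265875, -0.522189400]


@dataclass
class StageTruth:
    """Ground-truth per-epoch stage labels and RBD flags."""

    stages: np.ndarray  # array of stage-name strings
    rbd: np.ndarray  # bool, True only where stage == REM
    epoch_s: float = 20.0

    def __post_init__(self):
        self.stages = np.asarray(self.stages)
        self.rbd = np.asarray(self.rbd, dtype=bool)
        if self.stages.shape != self.rbd.shape:
            raise ValueError("stages and rbd must have the same length")
        if np.any(self.rbd & (self.stages != REM)):
            raise ValueError("RBD flags are only valid on REM epochs")

    def __len__(self) -> int:
        return len(self.stages)


@dataclass
class SynthSleepConfig:
    duration_s: float = 86400.0
    rate_hz: float = 500.0
    epoch_s: float = 20.0
    #: explicit [(stage, run_length_epochs), ...] or a 3x3 Markov matrix
    #: over (WAKE, NREM, REM); None selects the default Markov architecture.
    stage_arch: Sequence[tuple[str, int]] | np.ndarray | None = None
    band_amplitudes: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in DEFAULT_BAND_AMPLITUDES.items()})
    emg_tone: dict = field(default_factory=lambda: dict(DEFAULT_EMG_TONE))
    rbd_fraction: float = 0.05
    rbd_burst_gain: float = 4.0
    rbd_bursts_per_epoch: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        n = self.duration_s / self.epoch_s
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("epoch_s must divide duration_s")
        if not 0.0 <= self.rbd_fraction <= 1.0:
            raise ValueError("rbd_fraction must lie in [0, 1]")
        for s, amps in self.band_amplitudes.items():
            if any(a < 0 for a in amps.values()):
                raise ValueError(f"negative band amplitude for stage {s}")
        if any(a < 0 for a in self.emg_tone.values()):
            raise ValueError("negative EMG tone")

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_s / self.epoch_s))


def generate_stage_sequence(
    n_epochs: int,
    stage_arch: Sequence[tuple[str, int]] | np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample (or expand) a per-epoch stage label sequence."""
    if stage_arch is not None and not isinstance(stage_arch, np.ndarray) \
            and not (len(stage_arch) and isinstance(stage_arch[0], (tuple, list))):
        stage_arch = np.asarray(stage_arch)
    if stage_arch is None or isinstance(stage_arch, np.ndarray):
        P = DEFAULT_TRANSITIONS if stage_arch is None else np.asarray(stage_arch, dtype=float)
        if P.shape != (3, 3) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be 3x3 row-stochastic")
        states = np.empty(n_epochs, dtype=object)
        cur = 0  # start awake
        for i in range(n_epochs):
            states[i] = STAGES[cur]
            cur = rng.choice(3, p=P[cur])
        return states.astype(str)
    runs = list(stage_arch)
    total = sum(int(n) for _, n in runs)
    if total != n_epochs:
        raise ValueError(
            f"explicit stage runs cover {total} epochs but the recording has {n_epochs}")
    out = []
    for stage, n in runs:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        out.extend([stage] * int(n))
    return np.asarray(out)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    x = spsig.lfilter(_PINK_B, _PINK_A, rng.standard_normal(n))
    return x / x.std()


def generate_polysomnogram(
    config: SynthSleepConfig,
) -> tuple[PolysomnogramRecord, StageTruth]:
    """Synthesise a 500 Hz EEG/EMG recording with known stage labels.

    EEG = stage-amplitude-modulated delta (1.5 Hz) and theta (6.5 Hz)
    oscillators plus 1/f-ish broadband noise.  EMG = white noise at the
    stage's tonic amplitude; REM tone is the lowest.  RBD-flagged REM epochs
    additionally carry ``rbd_bursts_per_epoch`` phasic high-frequency bursts
    with 0.5-2 s rectangular envelopes at ``rbd_burst_gain`` times the tonic
    REM EMG amplitude (muscle twitches against atonia).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_ep = config.n_epochs
    spp = int(round(config.rate_hz * config.epoch_s))
    n = n_ep * spp

    stages = generate_stage_sequence(n_ep, config.stage_arch, rng)
    rbd = (stages == REM) & (rng.random(n_ep) < config.rbd_fraction)

    amp = {
        comp: np.repeat(
            np.array([config.band_amplitudes[s][comp] for s in stages]), spp)
        for comp in ("delta", "theta", "broad")
    }
    t = np.arange(n) / config.rate_hz
    phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
    eeg = amp["delta"] * np.sin(2 * np.pi * DELTA_HZ * t + phases[0])
    eeg += amp["theta"] * np.sin(2 * np.pi * THETA_HZ * t + phases[1])
    eeg += amp["broad"] * _pink_noise(n, rng)
    del amp, t

    tone = np.repeat(np.array([config.emg_tone[s] for s in stages]), spp)
    emg = rng.standard_normal(n) * tone
    del tone

    burst_amp = config.rbd_burst_gain * config.emg_tone[REM]
    for i in np.flatnonzero(rbd):
        for _ in range(config.rbd_bursts_per_epoch):
            dur = rng.uniform(0.5, 2.0)
            start = rng.uniform(0.0, config.epoch_s - dur)
            s0 = i * spp + int(start * config.rate_hz)
            s1 = s0 + int(dur * config.rate_hz)
            emg[s0:s1] += burst_amp * rng.standard_normal(s1 - s0)

    sec_stage = np.repeat(stages, int(round(config.epoch_s)))
    activity = np.abs(rng.standard_normal(sec_stage.size)) * np.where(
        sec_stage == WAKE, 1.0, 0.05)

    rec = PolysomnogramRecord(
        eeg=eeg, emg=emg, rate_hz=config.rate_hz, activity=activity)
    return rec, StageTruth(stages, rbd, config.epoch_s)


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

DEFAULT_PHOTOMETRY_OFFSETS = {
    "iso": {WAKE: 0.0, NREM: 0.0, REM: 0.0, "RBD": 0.0},
    "da": {WAKE: 0.5, NREM: -0.2, REM: 0.0, "RBD": 1.0},
    "ach": {WAKE: 0.6, NREM: -0.1, REM: 0.4, "RBD": 0.8},
}


@dataclass
class SynthPhotometryConfig:
    """Stage-dependent channel means plus white noise at the raw rate."""

    offsets: dict = field(default_factory=lambda: {
        ch: dict(v) for ch, v in DEFAULT_PHOTOMETRY_OFFSETS.items()})
    noise_sd: float = 0.3
    raw_rate_hz: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        if self.raw_rate_hz <= 0:
            raise ValueError("raw_rate_hz must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def generate_photometry(config: SynthPhotometryConfig, truth: StageTruth):
    """Multichannel photometry traces whose per-sample mean follows the
    epoch's state (WAKE/NREM/REM/RBD).  Returns a PhotometrySession."""
    from .photometry import PhotometrySession

    config.validate()
    if len(truth) == 0:
        raise ValueError("truth must be nonempty")
    rng = np.random.default_rng(config.seed)
    states = np.where(truth.rbd, "RBD", truth.stages)
    spe = int(round(truth.epoch_s * config.raw_rate_hz))
    channels = {}
    for ch, offs in config.offsets.items():
        try:
            base = np.array([offs[s] for s in states], dtype=float)
        except KeyError as e:
            raise ValueError(f"no offset for state {e.args[0]!r} on channel {ch!r}")
        trace = np.repeat(base, spe)
        trace += config.noise_sd * rng.standard_normal(trace.size)
        channels[ch] = trace
    return PhotometrySession(channels=channels, rate_hz=config.raw_rate_hz)


# ---------------------------------------------------------------------------
# histology section images
# ---------------------------------------------------------------------------


@dataclass
class DiskSpec:
    """One requested stain cluster: target pixel area, centroid, intensity."""

    area_px: float
    centroid: tuple[float, float]  # (row, col)
    intensity: float = 220.0


@dataclass
class DumbbellSpec:
    """Two equal disks rendered as one touching blob (watershed test case)."""

    radius_px: float
    centers: tuple[tuple[float, float], tuple[float, float]]
    intensity: float = 220.0


@dataclass
class SynthImageConfig:
    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 6.25
    pixel_area_um2: float = 6.25
    tissue_polygon: np.ndarray | None = None  # (n, 2) row/col vertices; None = full frame
    clusters: list[DiskSpec] = field(default_factory=list)
    dumbbells: list[DumbbellSpec] = field(default_factory=list)
    background_mean: float = 80.0
    texture_sd: float = 6.0
    texture_max: float = 180.0
    slide_intensity: float = 5.0
    seed: int = 0


def _disk_mask(shape, center, radius):
    rr, cc = skdraw.disk(center, radius, shape=shape)
    return rr, cc


def _radius_for_area(shape, center, target_area: float) -> float:
    """Pick the disk radius whose rasterization best matches the target pixel
    area (rasterized circles do not hit pi*r**2 exactly)."""
    r0 = max(np.sqrt(target_area / np.pi), 0.6)
    best_r, best_err = r0, np.inf
    for r in np.arange(max(0.6, r0 - 1.5), r0 + 1.5, 0.02):
        n = len(_disk_mask(shape, center, r)[0])
        err = abs(n - target_area)
        if err < best_err:
            best_r, best_err = r, err
    return best_r


def generate_section_image(config: SynthImageConfig):
    """Render textured tissue with intensity-elevated stain clusters.

    Returns ``(SectionImage, truth)`` where ``truth`` is a list of dicts with
    the realized per-cluster pixel area, centroid, and size bin (dumbbells are
    reported separately under the ``pair`` kind with their two centers).
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    if config.tissue_polygon is not None:
        tissue = skdraw.polygon2mask(config.shape, np.asarray(config.tissue_polygon))
    else:
        tissue = np.ones(config.shape, dtype=bool)

    tex = gaussian_filter(rng.standard_normal(config.shape), sigma=2.0)
    tex_sd = tex.std()
    if tex_sd > 0:
        tex = tex / tex_sd * config.texture_sd
    img = np.clip(config.background_mean + tex, 0.0, config.texture_max)
    img[~tissue] = config.slide_intensity

    truth: list[dict] = []
    for spec in config.clusters:
        r0, c0 = spec.centroid
        if not (0 <= r0 < rows and 0 <= c0 < cols) or not tissue[int(r0), int(c0)]:
            raise ValueError(f"cluster centroid {spec.centroid} outside the tissue")
        if spec.area_px < 1:
            raise ValueError("cluster area must be >= 1 px")
        radius = _radius_for_area(config.shape, spec.centroid, spec.area_px)
        rr, cc = _disk_mask(config.shape, spec.centroid, radius)
        img[rr, cc] = spec.intensity
        area = len(rr)
        truth.append({
            "kind": "disk",
            "centroid": (float(r0), float(c0)),
            "area_px": int(area),
            "size_bin": classify_area(area, config.pixel_area_um2),
        })
    for spec in config.dumbbells:
        pix = set()
        for center in spec.centers:
            r0, c0 = center
            if not (0 <= r0 < rows and 0 <= c0 < cols):
                raise ValueError(f"dumbbell center {center} outside the image")
            rr, cc = _disk_mask(config.shape, center, spec.radius_px)
            img[rr, cc] = spec.intensity
            pix.update(zip(rr.tolist(), cc.tolist()))
        truth.append({
            "kind": "pair",
            "centers": [tuple(map(float, c)) for c in spec.centers],
            "area_px": len(pix),
            "expected_labels": 2,
        })

    section = SectionImage(
        data=img,
        pixel_size_um=config.pixel_size_um,
        pixel_area_um2=config.pixel_area_um2,
        polarity="light-on-dark",
        tissue_mask=tissue,
    )
    return section, truth


def random_disk_specs(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_small: int = 8,
    n_medium: int = 8,
    n_large: int = 6,
    margin: int = 20,
    min_gap: float = 6.0,
    intensity: float = 220.0,
    min_coverage: float = 0.055,
) -> list[DiskSpec]:
    """Well-separated disk specs spanning the small/medium/large size bins.

    Placement is rejection-sampled so that circle boundaries stay at least
    ``min_gap`` pixels apart.  Total areas are resampled until the stain
    covers at least ``min_coverage`` of the frame, which keeps a
    95th-percentile threshold below the stain intensity.
    """
    n_px = shape[0] * shape[1]
    for _ in range(200):
        areas = np.concatenate([
            rng.uniform(5, 50, n_small),
            rng.uniform(60, 190, n_medium),
            rng.uniform(300, 700, n_large),
        ])
        if areas.sum() >= min_coverage * n_px:
            break
    else:
        raise RuntimeError("cannot reach the requested stain coverage")
    rng.shuffle(areas)
    placed: list[tuple[float, float, float]] = []
    specs = []
    for area in areas:
        r = np.sqrt(area / np.pi)
        for _ in range(2000):
            cr = rng.uniform(margin, shape[0] - margin)
            cc = rng.uniform(margin, shape[1] - margin)
            if all(np.hypot(cr - pr, cc - pc) >= r + pr_r + min_gap
                   for pr, pc, pr_r in placed):
                placed.append((cr, cc, r))
                specs.append(DiskSpec(float(area), (cr, cc), intensity))
                break
        else:
            raise RuntimeError("could not place all clusters; reduce counts")
    return specs


# ---------------------------------------------------------------------------
# group section series
# ---------------------------------------------------------------------------


@dataclass
class SynthGroupSeriesConfig:
    """Aligned per-animal section images with localized group effects.

    ``effect_blocks`` are (row0, row1, col0, col1) half-open ranges on the
    downsampled ROI grid; in non-control groups those ROIs are elevated by
    ``effect_d`` times the within-group SD.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "control": 8, "early": 8, "late": 8})
    control_label: str | None = None  # default: first group
    grid_shape: tuple[int, int] = (20, 20)
    effect_blocks: list[tuple[int, int, int, int]] = field(
        default_factory=lambda: [(5, 10, 5, 10)])
    effect_d: float = 2.0
    within_sd: float = 5.0
    base_intensity: float = 100.0
    pixel_noise_sd: float = 1.0
    block: int = 5
    pixel_size_um: float = 6.25
    seed: int = 0

    def validate(self) -> None:
        if len(self.group_sizes) < 2:
            raise ValueError("need at least 2 groups")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs n >= 2")
        if self.effect_d < 0:
            raise ValueError("effect size d must be >= 0")
        gr, gc = self.grid_shape
        for r0, r1, c0, c1 in self.effect_blocks:
            if not (0 <= r0 < r1 <= gr and 0 <= c0 < c1 <= gc):
                raise ValueError("effect block outside the ROI grid")


def generate_group_sections(config: SynthGroupSeriesConfig):
    """Returns ``(images, effect_truth, manifest)``.

    ``images`` maps group label -> list of SectionImage; ``effect_truth`` is a
    boolean ROI-grid mask of true-effect ROIs (all False when d == 0);
    ``manifest`` lists (animal_id, group).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    control = config.control_label or next(iter(config.group_sizes))
    gr, gc = config.grid_shape
    effect = np.zeros((gr, gc), dtype=bool)
    if config.effect_d > 0:
        for r0, r1, c0, c1 in config.effect_blocks:
            effect[r0:r1, c0:c1] = True

    images: dict[str, list[SectionImage]] = {}
    manifest = []
    for group, n in config.group_sizes.items():
        images[group] = []
        for i in range(n):
            roi = config.base_intensity + rng.normal(0.0, config.within_sd, (gr, gc))
            if group != control:
                roi[effect] += config.effect_d * config.within_sd
            img = np.kron(roi, np.ones((config.block, config.block)))
            img += rng.normal(0.0, config.pixel_noise_sd, img.shape)
            animal = f"{group}_{i:02d}"
            images[group].append(SectionImage(
                data=img,
                pixel_size_um=config.pixel_size_um,
                pixel_area_um2=config.pixel_size_um**2,
                polarity="light-on-dark",
            ))
            manifest.append({"animal_id": animal, "group": group})
    return images, effect, manifest
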