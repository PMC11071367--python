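# Methods

This note documents the models behind each pipeline stage, the parameters
that matter (with defaults and rationale), what the synthetic generators do
and do not emulate, numerical conventions, and known limitations. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal grid and band powers

A recording sampled at `rate_hz` (default 500 Hz) is cut into half-open
epochs `[t, t+epoch_s)` aligned to the recording start, `epoch_s = 20 s`,
0-based indices; the trailing partial epoch is dropped. Per epoch:

- **EMG RMS** `sqrt(mean(emg**2))` over the epoch's samples.
- **Relative band powers** from a Welch average of modified periodograms:
  1024-sample (2^10) Hamming-windowed segments with 50% overlap, constant
  detrend, partial trailing segment dropped (`scipy.signal.welch`). Band
  power is the sum of PSD bins whose center frequency falls in the band,
  as a percentage of the total over 0.3–80 Hz. Bands are half-open
  `[lo, hi)` except high-γ, closed at 80 Hz; 0.3–0.5 Hz and the 49–51 Hz
  line-noise notch are uncovered, so the seven bands sum to < 100%. At
  500 Hz the bin spacing is 0.488 Hz, giving 7 δ bins of 163 total — a flat
  spectrum therefore yields a mean δ share near 100·3.5/79.7 ≈ 4.4%, which
  the acceptance run checks empirically.
- **Artifacts**: an epoch is flagged when it contains non-finite samples,
  when its spectrum is degenerate (zero total power), or when either trace
  sits pinned at ±rail for at least `rate_hz/10` consecutive samples
  (digitizer saturation). The rail defaults to the recording's maximum
  absolute value and is configurable. Real artifact taxonomies are richer;
  this rule only needs to separate clearly corrupted epochs.

## Stage scoring

Three features per epoch — δ%, θ%/δ%, EMG RMS — are z-scored over the
non-artifact epochs of the recording and combined with equal weight:

    S_WAKE = z_emg      S_NREM = z_delta − z_emg      S_REM = z_td − z_emg

The stage is the argmax; exact ties resolve to WAKE; artifact epochs stay
UNSCORED. This is the minimal deterministic rule consistent with treating
the three factors as equally important; commercial scorers implement
proprietary variants of the same idea. A recording whose artifact fraction
exceeds 1% is marked `excluded` (the summary carries the reason) but is
still computed, so the exclusion is a flag, not a hard stop. Scoring
requires ≥10 non-artifact epochs and errors on zero-variance features.

## RBD detection

The atonia-loss threshold is computed from all REM epochs of the recording
in a single pass: `mean + 2*SD` of the epoch EMG RMS, with the sample SD
(ddof=1). Flagged-epoch contamination of the baseline is accepted in the
default mode; a robust mode (`median + 2·1.4826·MAD`) and an
iterative-exclusion mode are available but off by default. REM epochs
strictly above threshold are flagged; maximal runs of contiguous flagged
epochs form RBD events; the normalized metric is
`100 · n_events / n_REM_runs`, where REM "events" are maximal contiguous
REM runs (not epochs). Fewer than 3 REM epochs triggers a warning; zero REM
epochs yields no events and a missing normalized metric.

## Photometry

Raw traces are block-averaged down to 500 Hz (the raw rate must be an
integer multiple; 500 Hz passes through unchanged), then z-scored within
fixed, non-overlapping 60 s windows aligned to the trace start (the trailing
partial window is z-scored on its own samples; windows with SD < 1e-12 emit
zeros and a flag). Fixed rather than sliding windows were chosen because
only the window length is standard; epochs that straddle window boundaries
simply average the already-z-scored samples. Per-epoch channel values are
means over `[t, t+20 s)`; an epoch's state is RBD when flagged, otherwise
its stage, so RBD is disjoint from REM in aggregates. State contrasts are
paired two-sided t-tests on per-animal state means (df = n−1); animals
missing either state are dropped and counted. No isosbestic motion
regression or ΔF/F conversion is performed; the isosbestic channel is
carried as an ordinary channel and serves as a null comparison.

Note that within-window z-scoring removes between-window offsets: a state
contrast survives only through windows containing both states. REM/RBD
comparisons work because RBD epochs interleave with REM epochs at the 20 s
scale inside 60 s windows; contrasts between states that never share a
window would be attenuated toward zero. This mirrors the normalization it
reimplements and is a genuine property of the method, not of the code.

## Cluster quantification

Stain-high conversion (dark-on-light images are inverted), binarization at
the 95th percentile of within-tissue intensities (`mask = img >= threshold`),
Euclidean distance transform, watershed seeded from distance maxima of at
least half-pixel prominence (h-maxima, `h = 0.5` px), 8-connected labeling.
The h-maxima seeding suppresses sub-pixel ridge maxima that would over-split
single blobs while preserving the ≥1 px-deep saddle between genuinely
touching blobs; components that receive no marker keep their
connected-component identity. Filtering: area ≤ 1 px → `excluded_small`;
area > 15000 µm² → `excluded_artifact` (strict inequality: a cluster of
exactly 15000 µm² is retained); retained bins small (1,50] px,
medium (50,200] px, large (200,∞) px.

Unit convention: pixel-count rules are applied in pixels; µm² rules use
`pixel_area_um2`, default 6.25, which reproduces the original workflow's
arithmetic equating one 6.25 µm pixel with 6.25 µm²; the geometric
edge-based value (6.25² ≈ 39.06 µm²) is available by configuration. The
small-bin lower bound follows from the ≤1 px exclusion (retained minimum
2 px). Tissue surface comes from a supplied mask or, failing that, Otsu (or
triangle) thresholding of tissue against slide with hole filling; densities
are counts per mm² of surface.

A percentile threshold is only meaningful when stain occupies less of the
tissue than the percentile tail; conversely, on a stain-free textured image
the top 5% of background is segmented by construction. The synthetic image
generator therefore targets >5% stain coverage at a constant stain
intensity, which pins the threshold at the stain level and makes end-to-end
counts exact — a property of the fixture, not a general guarantee on real
slides, where threshold choice interacts with staining intensity and
background.

## Brain maps

Each aligned section is stain-high converted, divided by its mean intensity,
and mapped through the fixed affine x → 127.5·x, clipped to [0, 255]
(an image sitting at its own mean maps to mid-gray). The affine is identical
for every image, so between-group contrasts are preserved; the
divide-by-mean removes staining-batch intensity offsets. Non-overlapping
5×5 block means define ROIs (~31.25 µm edge at 6.25 µm pixels); partial
tiles are dropped. Per ROI: one-way ANOVA across groups; a ROI where every
animal holds the same value reports F = 0, p = 1 by convention. The Dunnett
many-to-one post hoc versus the control group is evaluated only for ROIs
with ANOVA p < α (post hoc analysis of significant ROIs), which is also what
keeps the per-ROI multivariate-t integration cheap. No multiple-testing
correction across ROIs is applied by default; Benjamini–Hochberg is
available by flag and records a divergence warning when enabled. Sections
are assumed aligned upstream; the module requires same-shape inputs.

## Statistics toolbox

- One-way ANOVA by direct sums of squares, df = (k−1, N−k).
- Tukey(-Kramer) via the studentized-range distribution on the pooled
  within-group MS; Fisher LSD is the same contrast unadjusted.
- Dunnett via the equicorrelated multivariate-t,
  ρ_ij = sqrt(λ_i λ_j), λ_i = n_i/(n_i+n_0), integrated by scipy's
  quasi-Monte-Carlo `multivariate_t.cdf` with a fixed internal seed and
  20 000·m integration points (integration error well under the 5e-4
  documented tolerance); the single-comparison case is computed exactly
  from the univariate t.
- t-tests: paired df = n−1 (a zero-variance, zero-mean difference reports
  t = 0, p = 1); unpaired defaults to Welch (the safer choice when the
  original software's pooled default is unknown), pooled by flag.
- Two-way group×sex ANOVA via OLS with Type-II sums of squares
  (statsmodels); the interaction is the headline statistic since designs
  are near-balanced.
- ROUT, specialised from its regression formulation to the constant model
  for plain samples: robust location = median; robust scale
  RSDR = P68 · n/(n−K) with K = 1 fitted parameter, where P68 is the
  68.27th percentile of absolute residuals; residual t-scores (df = n−1)
  are screened by Benjamini–Hochberg at Q (default 5%), iterating the
  robust fit on unflagged points to convergence. Flagged values are
  reported, never silently removed. Applied per group by default.
- p-values are floored at 1e-300, never reported as 0.

## Synthetic data generators

All generators are pure functions of (config, seed) via one
`numpy.random.default_rng` per call; no global state.

**Polysomnograms.** Stage sequences come from a per-epoch Markov chain over
(WAKE, NREM, REM) with stationary distribution ≈ 50/40/10% and mean REM
runs of 5 epochs (mouse-like 24 h architecture), or from explicit
(stage, run-length) lists that must tile the recording exactly. EEG is the
sum of a 1.5 Hz δ oscillator and a 6.5 Hz θ oscillator with stage-dependent
amplitudes (WAKE 0.5/1.0, NREM 3.0/0.5, REM 0.3/2.5) plus unit-variance
1/f-shaped broadband noise; these defaults separate the staging features by
≥1.8 z between stages (computed analytically from band-power shares before
any test was run) while remaining degradable through the config. EMG is
white noise at stage-dependent tonic amplitude (WAKE 1.0, NREM 0.4,
REM 0.1; REM strictly lowest). RBD epochs — a fraction `rbd_fraction`
(default 0.05, sparse loss-of-atonia that keeps the single-pass mean+2SD
baseline usable) of REM epochs — receive 2 phasic bursts per epoch with
rectangular envelopes of 0.5–2 s and white-noise amplitude
`rbd_burst_gain × tonic REM amplitude` (default gain 4; the gain is
expressed in units of the REM EMG sample SD, i.e. the atonic tone, the
physically meaningful scale for a muscle twitch). A 1 Hz activity channel
is generated for format parity and unused downstream. Not emulated:
spindles, K-complexes, real EEG nonstationarity, mixed-stage epochs —
staging accuracy on this generator is an upper bound, not a claim about
recordings.

**Photometry.** Each channel is a per-epoch state offset (WAKE/NREM/REM/RBD)
plus white noise (σ = 0.3) at 500 Hz; isosbestic offsets are 0 in every
state. Default dopamine offsets put RBD 1 z above REM. No optics,
bleaching, or motion artifacts.

**Section images.** Textured tissue (mean 80, smoothed noise SD 6, clipped
below 180) on a dark slide, with disk-shaped stain clusters at constant
intensity 220; the disk radius is searched so the rasterized area matches
the requested pixel area within ±2 px, and the truth records the realized
area and bin. Dumbbells (two equal disks overlapping by less than one
radius) exercise watershed splitting. `random_disk_specs` places
well-separated disks spanning all three bins and resamples areas until
stain coverage exceeds 5.5% of the frame (see the percentile note above).

**Group section series.** Per animal, ROI values are
`base + N(0, within_sd)` with `within_sd = 5` on base 100; in non-control
groups the configured effect blocks are elevated by `d · within_sd`
(default d = 2, n = 8 per group, 20×20 ROI grid with one 5×5 effect
block); images are the ROI values expanded 5× with small pixel noise.
Dividing by the image mean during normalization couples the effect ROIs
weakly into the null ROIs (an ~0.1 σ shift at the default geometry), which
is why the null false-positive bound in the recovery benchmarks is 7%
rather than 5%.

## Problem sizes used by the benchmarks

RBD/oracle agreement: 1000 random grids. Burst recovery: seeds ×10 at 4 h
per recording (≈36 burst epochs accumulate). Staging: seeds ×5 at the full
24 h (4320 epochs). Band powers: 200 white-noise epochs. Photometry:
20 seeds × 11 animals × 20 min sessions with explicit stage architecture
and 40% of REM epochs flagged (so every animal holds both states). Clusters:
100 images with a planted 1 px speck and a 2601 px (16 256 µm²) blob in a
reserved strip. Dumbbells: 100 cases, radii 6–12 px, center distance
1.2–1.8 radii. ROI maps: 20 null seeds and 5 effect seeds of the default
series. Toolbox: 10 000 null ANOVA replicates (6 groups, n = 9), 1000 ROUT
replicates each for the planted-outlier and clean cases. These sizes were
chosen so each benchmark's sampling error is small relative to the bound it
checks while the whole run stays in the minutes range on one CPU.

## Known limitations

- The staging rule is linear and recording-standardized; it will mis-rank
  stages on recordings whose feature distributions are strongly skewed or
  whose stage mix is extreme (e.g. near-zero REM).
- The RBD baseline includes flagged epochs; at high RBD prevalence the
  threshold inflates and sensitivity falls — the robust and iterative
  modes exist for that regime.
- The percentile threshold ties segmentation to stain abundance (see
  above); absolute-intensity thresholds would decouple them but need
  calibrated scanners.
- The ROI maps assume upstream section alignment; only rigid same-shape
  inputs are supported.
- ROUT's RSDR small-n correction uses the published constant-model form;
  for n < ~10 its false-positive rate is conservative rather than exact.
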