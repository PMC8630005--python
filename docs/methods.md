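# Methods

`smpet` analyses two-colour single-molecule PET (photoinduced electron
transfer) fluorescence data: intensity time traces of surface-tethered
protein molecules in which a conformational change switches a fluorophore
off (quenched, "closed") or on (fluorescent, "open") in each of two
spectrally separate channels, one channel per conformational coordinate.
This note records the models, numerical choices and known limitations of
each stage.

## Generative model (trace_simulator)

The hidden dynamics are a continuous-time two-state telegraph process on a
single shared clamp coordinate. While the clamp is open, closure attempts
fire at rate `k_close` (min⁻¹); each attempt is either

- **coupled** (probability `1 − p_uncoupled`): both reporter channels quench
  together and recover together after an Exp(1/k_open) sojourn; or
- **uncoupled** (probability `p_uncoupled`): a failed closure attempt that
  quenches one randomly chosen channel alone for an independent
  Exp(1/k_open) sojourn while the clamp — and the other channel — stay open.

Uncoupled events are quench-initiated only; their later single-channel
re-openings are consequences and are logged as `uncoupled_open`. This
reproduces the phenomenology of concerted two-channel fluctuations with a
minority of one-channel quench-only excursions whose lifetimes match the
opening kinetics. Per-channel photobleaching is an independent exponential
event and is absorbing: a bleached reporter never recovers, which is what
makes bleaching distinguishable from PET quenching at all.

Three modes: `atp_cycling` (the process above), `apo` (no coupled closures;
per-channel spontaneous excursions at rate `k_close · p_uncoupled` each,
matching the rare quench-only events seen without nucleotide), and
`ampnp_onecolour` (single channel, one irreversible closure at rate
`k_close`; after oxygen application at `o2_application_s` a quenched — not
bleached — reporter recovers after an Exp(`dspo_mean_delay_s`) delay,
modelling dye-sensitized photo-oxidation of the quenching tryptophan).

Event times are drawn in continuous time and binned to the frame grid:
channel states are sampled at frame times `t_k = k·Δt`, so a pair of
transitions that cancels within one frame is invisible, the simplest model
of frame-rate-limited observation. The discrete event log records the first
frame at which each surviving transition is visible. The simulator is a
pure function of (config, seed).

Defaults follow the acquisition geometry of the experiments the analysis is
designed for: 9-minute traces (540 s), 0.3 s/frame two-colour or 1.0
s/frame one-colour, `k_close` = 1 min⁻¹ and `k_open` = 5 min⁻¹ (the
single-molecule closure/opening regime), oxygen application at 600 s,
512×512 px frames at 130 nm/px.

### Rendering and noise

The trace-level fast path maps open frames to `level_open` expected counts
(default 500) and quenched/bleached frames to `level_background` (default
50), with Poisson shot noise in photon number and additive Gaussian read
noise (default rms 5). These defaults give a step signal-to-noise ratio of
about 19, comparable to a bright, well-aligned TIRF acquisition.

The image path renders each molecule as a pixel-integrated 2-D Gaussian
(default σ = 1.3 px, 2000 photons/frame when open) on a uniform background
(20 photons/px), with Poisson + Gaussian camera noise and a single gain
scalar. EMCCD gain-register statistics are deliberately collapsed into that
scalar plus read noise; excess-noise modelling is out of scope because the
detection logic under test is threshold-based, not photon-counting.
Spots are placed uniformly at random with a minimum separation of 6 σ_psf
(sparse fields, as sub-nM surface densities give in practice; 4 σ_psf is
enforced as a hard lower bound, matching the localizer's merge radius).
Channel-2 positions can be warped by a configurable affine misalignment so
registration is exactly testable. Fiducial-bead frames render the same
field in both channels at 5× molecule brightness.

What the synthetic data do **not** emulate: dye blinking (the experimental
buffer includes Trolox and an oxygen scavenger precisely to suppress it; a
blinking rate can be added for robustness studies but is off by default),
stage drift (hardware-corrected in the reference setup), chromatic PSF
differences, FRET cross-talk, and physically calibrated photon budgets.
Passing tests therefore demonstrate correctness of the analysis logic under
the stated noise model, not robustness to every artifact class of real
recordings.

## Localization, registration, co-localization (tirf_image_pipeline)

Spots are local maxima above `background median + threshold_k ×
1.4826·MAD` (default `threshold_k` = 5), refined to sub-pixel position by
an intensity-weighted centroid over a `(2·ceil(3σ_psf)+1)²` window; maxima
closer than 4 σ_psf merge to the brighter one. Centroid refinement replaces
full PSF least-squares fitting: at these spot densities its ≤0.05 px
accuracy is far below the 2 px co-localization tolerance.

Channel registration is a least-squares affine fit (channel 2 → channel 1)
on fiducial beads paired by mutual nearest neighbour within a coarse radius
(default 10 px). At least three non-collinear matches are required;
collinearity is tested via the second singular value of the centred
coordinates. A residual RMS above 1 px triggers a warning. An affine map
replaces the elastic registration used with real optics because it is
injectable by the simulator and exactly recoverable; elastic warps are out
of scope.

Co-localization pairs spots greedily by ascending mapped distance,
one-to-one, keeping pairs within `tol_px` (default 2 px). The reference
image for pairing is the per-channel maximum projection of the first 10
frames, when both reporters are still predominantly fluorescent. Traces are
read out per frame as the maximum pixel within a square ROI (default
half-width 3 px ≈ 2–3 σ_psf) centred on each channel's own spot; an
integrated-intensity mode exists but is not the default.

Coordinates are 0-based (x, y) pixel units with pixel centres at integers;
time is always `frame × frame_interval_s`.

## Step detection (step_detection)

Traces are idealized to exactly two levels. The detector is Gaussian
smoothing (σ = 1.5 frames, kernel truncated at 4σ, reflective boundary)
followed by the multiscale product: first-derivative-of-Gaussian edge
kernels at dyadic scales {1, 2, 4} frames, responses multiplied pointwise.
A genuine step responds coherently at every scale, so the product grows as
amplitude³ while incoherent noise is suppressed; with an odd number of
scales the product's sign preserves the step direction. Each kernel's
positive lobe is normalized to unit sum so a clean step of height h
responds with peak ≈ h at every scale.

Numerical choices:

- **Threshold calibration.** A candidate must exceed `threshold_c` (default
  3) times the robust noise level of the detail signal *at every scale*,
  i.e. the product threshold is `∏_s (c · 1.4826 · MAD(detail_s))`. The MAD
  of the product signal itself is not a usable noise floor: a product of
  three near-zero details is so leptokurtic that its MAD badly
  underestimates the tail, and noise excursions coherent across the (highly
  correlated) scales then pass at a rate of ~0.1 false steps per flat
  trace. With per-scale calibration the measured false-step rate is 0.002
  per trace at step SNR 5, with recall 1.0.
- Candidates within `max(scales)` frames of either trace end are discarded
  (wavelet edge artifacts); candidates closer than `min_separation_frames`
  (default 3) are pruned keeping the larger |product|, ties to the earlier
  frame.
- Step amplitudes are differences of flanking level medians and must exceed
  `min_relative_amplitude` (default 0.25) of the trace's 5–95 percentile
  range; sub-threshold steps are removed weakest-first with re-measurement.
- Levels are assigned fluorescent/quenched by weighted 2-means on segment
  medians against the midpoint of the two level means; adjacent same-label
  segments merge. If the two level means are closer than one robust noise σ
  the trace is labelled single-level, with zero steps, and flagged.
- The detector is equivariant under positive affine intensity rescaling and
  (to ±1 frame) under time reversal.

A terminal bleach level is *not* a third level here: quenched and bleached
intensities are one "low" level at detection time, and bleach
classification happens downstream.

## Kinetics (kinetics)

Same-direction steps in the two channels within `sync_window_frames`
(default 6 frames = 1.8 s at 0.3 s/frame) form one synchronous transition,
matched greedily one-to-one by ascending |Δframe| (ties toward the earlier
green frame; the window contains at most a few candidates, and on such
instances greedy matching equals the exhaustive minimum-|Δ| assignment,
which is tested). Unmatched steps are non-synchronous. A terminal quench
with no later recovery in its channel is a bleach candidate and excluded
from transition counts; conservatively, a *matched pair* of terminal
quenches is also treated as a candidate double bleach rather than a final
closure, since the two cannot be distinguished.

The non-synchronous share is reported under both conventions —
`100·N_ns/N_s` (headline) and `100·N_ns/(N_s+N_ns)` — because published
per-construct counts are only consistent with the ratio-to-synchronous
convention.

Dwells are the intervals between consecutive steps per channel, with
`duration = frames × Δt`. Intervals touching a trace boundary are censored;
intervals ended by a bleach candidate are right-censored (default) or drop
the whole channel trace, per `bleach_tail_policy`. Censored dwells are
excluded from fits with no survival correction: the reference analysis
carries the same fast-event bias from its short observation window, so
bias-matching beats bias-correcting. (Quantitatively: at 9-minute windows
the completed open dwells of a 60 s process sit ~13% below the generative
mean; the recovered `k_c` inherits a bias of that order, which is why the
end-to-end recovery tolerance is ±25%.)

Dwell-time distributions are summarized as cumulative-sum curves (sorted
durations vs cumulative count — bin-free, unlike histograms) and fitted by
least squares to `N(t) = N_tot·Σ aᵢ(1 − e^{−t/τᵢ})` with `Σaᵢ = 1`,
`N_tot` fixed at the observed dwell count, one or two components,
multi-start initialization (τ from 0.5×, 1×, 2× the sample mean). Model
choice is by Bayesian information criterion by default (`n·ln(RSS/n) +
k·ln n`); fixed mono/bi selection is available. At least 10 uncensored
dwells are required for a mono fit, 25 for bi; all-equal durations and
non-convergence are errors, never a silent fallback. Amplitude-weighted
mean rate constants are `k = 1/(Σ aᵢτᵢ)`, converted to min⁻¹: `k_c` from
open (fluorescent) dwells, `k_o` from closed (quenched) dwells. Amplitude
normalization is enforced before the mean-rate formula.

One-colour AMP-PNP data are classified by dye-sensitized photo-oxidation
logic: a quench step is PET-confirmed iff the same trace shows a recovery
step at or after the oxygen application time; a quench with no recovery is
unconfirmed (indistinguishable from bleaching); a recovery before oxygen is
flagged anomalous. When this classifier is scored against simulation ground
truth, the denominator contains only *observable* events: a quench inside
the detector's boundary-discard margin, or a recovered state shorter than
the minimum step separation (recovery immediately followed by bleach),
cannot be classified by any frame-limited detector — the same censoring
logic the dwell analysis applies.

Bulk quenching decays are fitted as `I(t) = I_∞ + Σ Aᵢ·e^{−t/τᵢ}` (two
components, amplitudes normalized over the decaying part) with the same
mean-rate convention. Rate-ratio free-energy conversion uses
`ΔΔG = |−RT·ln(k/k′)|` with R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and temperature
in kelvin.

## Pipeline and reporting (cli_and_config)

`run_pipeline` executes simulate → (extract) → detect → kinetics from one
validated YAML config (unknown keys rejected before any computation) and
writes CSV/TIFF/JSON artifacts plus a manifest with config hash, package
version, per-stage SHA-256 checksums and wall times; identical config +
seed reproduces identical checksums. The trace-level fast path is the
default; `render_images: true` exercises the full image path.

`report` writes a summary table (counts, both percentage conventions, per
colour `k_c`/`k_o`) and cumulative-sum plots with fitted curves. Rate
uncertainties are bootstrap standard deviations over molecules (B = 200,
seeded) — a different estimator from repeat-experiment scatter, which has
no synthetic analogue; empty dwell sets yield "n/a" cells with a warning,
not an error.

## Problem sizes used in the validation suite

The test and acceptance runs use trace-level simulations of 150 two-colour
molecules × 1800 frames at 0.3 s/frame for parameter recovery, 500
noise-augmented telegraph traces for detector operating characteristics,
64×64 px × 300-frame stacks for the image path, 2000-dwell samples for
mixture recovery, and 120 one-colour molecules for DSPO classification —
sizes at which the statistical tolerances stated in the tests are
comfortably resolved.

## Known limitations

- Two-level idealization only; multi-level staircases (e.g. partial
  quenching, multi-step bleaching) are out of scope.
- No hidden-Markov or Bayesian change-point inference; no survival
  correction for censored dwells.
- The distribution of non-synchronous *open* intervals is not constrained
  by published data; the simulator exposes it through the same `k_open`
  rather than asserting an independent value.
- Affine (optionally polynomial) registration only; elastic warps are not
  modelled.
- The co-localization tolerance (2 px) and ROI half-width (3 px) are
  package defaults, not published values.
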