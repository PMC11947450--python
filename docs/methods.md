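# Methods

## Motion-cloud synthesis

A motion cloud is generated in the Fourier domain as an amplitude envelope
times uniform random phases, inverse transformed to luminance frames. The
envelope is separable:

* **Spatial frequency** — Gaussian in log frequency centered on the central
  frequency `f0` with log-scale `σ_log = sf_bandwidth / f0`, so that the
  dispersion linearized at `f0` equals the bandwidth in cycles/degree. A
  bandwidth much larger than `f0` (e.g. 0.4 cpd around 0.04 cpd) therefore
  spreads energy over many octaves, clipped implicitly by the frequency grid.
* **Orientation** — wrapped Gaussian (period 180°) with standard deviation
  equal to the orientation bandwidth in degrees. Orientation convention:
  0° = vertical edges, counterclockwise, arithmetic mod 180°. Whether the
  bandwidth parameters of the original generative package are standard
  deviations or full widths is not fixed by their names; we adopt standard
  deviations of the amplitude envelopes, which makes the measured
  orientation-*energy* dispersion of a bandwidth-`b` cloud `b/√2` (energy is
  amplitude squared), a relation the tests verify directly.
* **Drift** — a rigid translation of the whole texture, orthogonal to the
  central orientation (rightward for 0°), at `temporal_freq / f0` degrees per
  second. At 60 fps (the assumed refresh rate; 300 frames = 5 s) a 1 Hz,
  0.04 cpd cloud advances one period per 60 frames. This is the simplest
  temporal model consistent with a pure drift specification: the temporal
  bandwidth is zero.

**Contrast normalization.** The zero-frequency component is removed, making
every rendered frame exactly zero-mean, and the movie is rescaled
symmetrically, `L = 0.5 + 0.5·x / max|x|` over the whole rendering. This uses
the full display range while guaranteeing a mean luminance of exactly 0.5 —
the conservation property the analyses assume. A plain min–max variant is
available (`contrast="minmax"`); for these symmetric random fields the two
differ negligibly. Note that the peak-normalization makes the RMS contrast of
a rendering depend weakly on its size and length (the global maximum of a
Gaussian field grows like √(2 ln N)); the reference center-magnitude quantity
inherits this sensitivity, which is why its tolerance is wide.

**Seeding.** Each rendering's random stream derives from
`SeedSequence([spec.seed, rendering_id])`: renderings are mutually
independent but individually reproducible bit-exactly.

**Protocol sequencing.** Presentation orders are balanced over (condition,
rendering, repeat) with no two consecutive trials sharing a condition. The
sequencer draws uniformly among allowed conditions but forces any condition
holding more than half of the remaining trials (the feasibility-preserving
greedy), so every arrangeable multiset is arranged; two conditions yield
strict alternation.

## Image statistics

* **Directionality** — gradients from the separable 5×5 Sobel pair
  (binomial smoothing [1 4 6 4 1] ⊗ derivative [−1 −2 0 2 1]), folded mod
  180°, binned at 1° into 180 bins and normalized to probability mass. Votes
  are weighted by squared gradient magnitude by default (energy weighting);
  a pixel-count mode is provided since plugin implementations differ.
  Gaussian smoothing (σ = 2 bins, circular) applies to across-image means
  only. A constant image returns the uniform histogram with a warning.
* **Radial spectrum** — centered 2-D power spectrum averaged within
  integer-Euclidean-radius annuli; the axis converts cycles/image to
  cycles/degree via the display angular size `2·atan(width/2D)` or the
  camera field of view `2·atan(sensor/(2·crop·focal))`. Annulus means times
  annulus counts sum to total spectral power (Parseval), which the tests
  assert.
* **Predictability maps** — frames are center-cropped (256×512 when larger),
  2× block-downsampled, Gaussian lowpass filtered (σ = 2 px — a mild
  anti-aliasing choice; the cutoff is configurable), mean-subtracted and
  circularly autocorrelated via the FFT; the central 51×51 window is
  averaged over frames. Coefficients are divided by the frame variance
  (center = 1) by default; the raw variant is exposed.

## Gabor-bank V1 model

Kernels follow the standard image-processing Gabor parameterization: for
wavelength λ, the envelope scale along the wave is
`σ_wave = λ/π · √(ln2/2) · (2^B+1)/(2^B−1)` with B = 2.38 octaves, and the
scale along the stripes is `σ_wave / γ` with aspect ratio γ = 0.55 — an
elongation along the stripes that yields an orientation-tuning half-width at
half-maximum of ≈21.4° against full-contrast gratings, matching mouse V1.
Under this parameterization the HWHM *increases* with γ (a larger γ shortens
the stripe-axis envelope). The bank spans 180 orientations × 5 spatial
frequencies {0.01, 0.02, 0.04, 0.06, 0.08} cpd = 900 kernels, built lazily
and cached.

Responses are quadrature-pair (complex) magnitudes — an ideal-phase filter,
assuming uniform phase representation. Two numerical corrections keep the
contracts exact:

* the even (cosine) kernel's DC leakage is removed by subtracting a scaled
  envelope, so uniform fields give exactly zero magnitude;
* the odd kernel is then rescaled so both quadrature legs respond equally to
  their optimal grating, restoring exact phase invariance of the magnitude
  (the DC correction would otherwise unbalance them by a few percent at this
  large SF bandwidth).

Every filter is normalized to answer 1.0 to its optimal full-contrast grating
(luminance 0.5 ± 0.5). Kernels are clipped to the available frame when
necessary and the normalization constant is recomputed for the clipped
kernel, so normalized magnitudes remain comparable — the same implicit
truncation a finite display imposes.

Response grids sample every 4×-downsampled pixel of the central 30°×30°
patch (37×37 sites at the reference pitch of 0.833°/site; grid spacing is
patch extent / (sites − 1)). Frames are replicate-padded before the
correlation so border sites also answer zero to uniform fields. The center
site of an odd-sized grid is the exact middle; an even grid takes the
lower-index middle site (deterministic tie-break).

## Tuning-only and suppression models

`c(o, b)` is the center-site magnitude averaged over the five spatial
frequencies (and frames). The tuning-only model scales it by a single factor
`w_t = mean(a)/mean(c)` matching the grand mean of measured amplitudes
`a(o, b)` over the five orientation bins and both conditions. The
suppression model divides each per-frame, per-frequency center magnitude by
`1 + w_s · max(0, s + t)` before pooling (frequency mean, then frame mean —
following the equation's order; the alternative pooling order is not exposed),
where `s(o, f, b)` is the mean magnitude of same-(o, f) filters over an
annulus with fitted radii `lim_i < lim_o` within 7.5–15°, strict
inequalities in grid units. At `w_s = 0` and `w_c = w_t` the suppression
model reduces to the tuning-only model exactly.

**Fitting.** Mean squared error between predictions and the orientation ×
condition target means, all conditions jointly. The five parameters are
searched by bounded Nelder–Mead from 100 uniform random restarts (seeded),
with infeasible proposals (inverted or empty annuli) given a large penalty.
Because the annulus radii act on the loss only through the *discrete* set of
enclosed sites, a pure simplex stalls on the plateaus between consecutive
site distances; the search therefore finishes with a discrete refinement
that enumerates every distinct annulus within bounds and refits the three
continuous parameters per annulus (from the incumbent and from a neutral
no-suppression start), then polishes the winner. On noise-free
model-generated targets this recovers the generating parameters to numerical
zero loss, up to the genuine non-identifiability of annuli whose membership
sets coincide or whose surround never crosses threshold. Surround averages
inside the fit use distance-sorted prefix sums, making each objective
evaluation O(1) in grid sites.

Recruitment regression is no-intercept least squares, `β = Σxy/Σx²`;
goodness of fit is the mean-corrected `R² = 1 − SS_res/SS_tot` (negative
when the model underperforms the mean). Response modulation is
`(broad − narrow)/(broad + narrow)` per orientation bin — positive for
stronger broadband responses, the same operator as the OMI, which makes
off-center-tuned units come out positive.

## Trial-based analyses

Amplitudes are stimulus-window means minus a 1-s baseline mean per trial; a
neuron's condition response is the median over trials. The stimulus window
defaults to 2 s (the specification "first 2–3 s" is ambiguous; 2 s matches
the shortest stimulus used and is configurable). Responsiveness is a
one-sided Mann–Whitney U test (stimulus > baseline, α = 0.05): exact
enumeration for tie-free samples of ≤ 12, tie/continuity-corrected normal
approximation otherwise; an all-tied degenerate input warns and reports
p = 1. Both responder labelings are emitted: *common* (significant in all
conditions) and *condition-only* (significant in exactly one).

The shuffle null for `BW_SI` permutes trial labels across the three
bandwidth conditions (1000 shuffles, seeded, vectorized); condition-mean
summaries are recomputed per shuffle with the same summary statistic
(median). Above the 95th percentile → selective for that band; below the
5th → mixed-selective for the other two; otherwise nonselective. By
construction the per-band false-positive rate on exchangeable data is ≈5%,
which the calibration tests verify at 10,000 null neurons.

ROC areas use the rank statistic with half credit for ties (equal to
exhaustive pair counting, property-tested). Preferred orientation is the
argmax of the 1°-resolution linear interpolation of the five-point tuning
curve — localization is limited to about half the 22.5° sample spacing —
with ties broken toward 0°, then toward the more negative orientation; a
neuron is *tuned* when its peak−trough depth exceeds the population median
depth. Sparse-noise receptive fields take the significant location with the
largest median amplitude (row-major on exact ties); the field *size* has no
canonical estimator, so we report the equivalent diameter of the total
significant area (12°-square locations), flagged as a package choice.

The mixed-effects model regresses response modulation on surround
modulation, orientation tuning and center response with a random animal
intercept, fitted by maximum likelihood so the likelihood-ratio test against
the animal-only model is valid (3 df χ²). When the random-intercept MLE sits
at the zero boundary (the mixed fit cannot beat OLS in likelihood) the fixed
effects are taken from OLS exactly; a single animal falls back to OLS with a
warning. Bonferroni-adjusted α is reported for an explicitly declared number
of planned comparisons — never inferred.

## Behavioral staircase

Difficulty moves −3° after a correct response and +8° after an error,
clamped to configurable floor/ceiling bounds (no canonical values exist, so
they are explicit configuration; defaults 0–90°). The zero-drift point of
this bounded Markov chain fixes accuracy at `8/(8+3) = 72.7%` for any
observer stationary there, verified analytically and by a 10⁶-trial
simulation. Simulated observers are logistic in orientation difference with
a 0.5 guess floor and a lapse parameter — analytically invertible, which the
threshold tests exploit. Session thresholds: mean difficulty at the last 8
reversals after discarding the first 2 (standard staircase practice; the
source procedure names no extraction method), with the terminal difficulty
emitted as an alternative estimator. Psychometric summaries bin percent
correct (a single 40–50° pooling bin is supported) and interpolate the
72.7% crossing; extrapolation outside the observed range is refused. Bias
correction: after ten randomized trials, a two-sided binomial test (α =
0.05) on the trailing 20 chosen sides pushes the target toward the
non-preferred side (probability 0.8) when a side bias is detected; a
significant excess of stay-choices raises the switch probability instead.

## Synthetic data generator

Each ground-truth neuron has a preferred orientation (uniform or
cardinal-biased), a wrapped-Gaussian orientation tuning width (mean 20°,
clipped at 5°), a log-normal preferred SF around 0.04 cpd, a log-domain SF
width in octaves (mean 1.5), a log-normal response gain (median 0.05 ΔF/F,
near reported mean amplitudes), additive Gaussian trial noise (σ = 0.02
ΔF/F), an animal id, and per-condition suppression multipliers. A trial's
expected amplitude is gain × orientation overlap × SF overlap × suppression
multiplier (full-field only); baselines are noise-only.

The overlap kernel is closed-form: a neuron's amplitude to a random-phase
band is the square root of the stimulus energy its Gaussian passband
captures, and with the band's total energy fixed this gives
`(w_n²/(w_n²+w_s²))^¼ · exp(−d²/(4(w_n²+w_s²)))` per feature dimension
(wrapped orientation in degrees; SF in octaves, with a bandwidth of `b`
cpd around `f0` entering as `log2(1 + b/f0)`). Energy conservation is what
makes the generator reproduce the study's asymmetry: widening the
*orientation* band recruits off-tuned neurons (and, with narrow-specific
suppression release, roughly doubles responsive counts), while widening the
*SF* band under bandwidth-independent suppression leaves recruitment
approximately unchanged.

Suppression regimes: `none`, `narrow-specific` (0.5/0.7/0.9 for
narrow/mid/broad orientation bandwidth — suppression released by broadband
orientation content), `uniform` (0.5 everywhere — for SF protocols), and a
center-surround regime (0.4/0.4/0.85/0.85 for narrow/SF/ORI/mixed). Spike
trials are Poisson counts with rate = baseline + gain-normalized drive ×
rate gain.

**What the generator does not emulate:** correlated population noise, calcium
indicator dynamics (noise lives on amplitudes, not raw traces; an optional
trace mode is out of scope), eye movements, behavioral-state modulation
(carried only as a pass-through flag), and any spatial receptive-field
structure beyond the center/full-field dichotomy. Passing tests therefore
demonstrate the *analysis chain's* correctness and calibration on data with
the assumed statistical structure — not that real V1 data satisfy that
structure.

## Problem sizes used in tests and the acceptance script

Synthesis-based checks run at a 640×640 native frame (≈0.21°/px, the
reference pitch that yields 37×37 grid sites after 4× downsampling) with
40–60 frames and 8–16 renderings per condition; calibration checks use
10,000 null neurons; the staircase equilibrium check simulates 10⁶ trials;
suppression-fit recovery uses 25×25-site grids with 5 orientations × 3
frequencies × 4 frames. These sizes are the package's test-scale defaults;
all operations accept the full-scale parameters (300-frame renderings,
37×37 grids, 900 filters) through the same interfaces.

## Known limitations

* The motion-cloud bandwidth parameters are dispersions of *amplitude*
  envelopes; implementations that interpret them as energy dispersions or
  full widths will measure correspondingly different histogram widths.
* Peak (full-range) contrast normalization ties RMS contrast to rendering
  size; fixed-RMS normalization would decouple them but is not the display
  convention emulated here.
* Narrow orientation bandwidths at low central SF are under-resolved on a
  finite display (few Fourier modes on the frequency ring), so measured
  orientation dispersions at 0.04 cpd are dominated by mode discreteness;
  bandwidth-recovery checks therefore probe at higher central SF.
* `MixedLM` likelihood-ratio p-values for variance-adjacent hypotheses are
  asymptotic; the package uses the LRT only for fixed-effect inclusion.
* The suppression model's annulus radii are identifiable only up to annuli
  with identical membership sets (and not at all when the surround never
  crosses threshold); fitted radii should be read as representatives of
  their equivalence class.
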