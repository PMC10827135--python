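# Methods

This note documents the models, estimators and numerical choices behind
`kymoflux`, and what the synthetic validation does and does not establish.

## Physical setting and units

A DNA tether (lambda DNA, 48.5 kbp) is stretched to ~5 pN between two
optically trapped beads and imaged by confocal line scanning at a 42.4 ms
line time. Fluorescently labeled chromatin remodelers (red channel) and
nucleosomes (green channel) appear as lines in the kymograph; a particle
tracker exports per-particle (time, position) tables that this package
consumes. All positions are micrometres along the tether; base pairs are
converted through a single constant, 0.072/225 ≈ 3.2×10⁻⁴ µm/bp, the
contour-per-bp implied by the instrument's stated 72 nm ≈ 225 bp 1D
resolution under tension. One pixel is taken as 0.072 µm for the same
reason, so "one pixel of localization noise" is a 72 nm Gaussian error.

## Rolling-window diffusion analysis

Instantaneous diffusion is estimated on 20-frame windows advanced one frame
at a time. Within a window, the time-averaged MSD is computed over all
observed frame pairs at lags 1–5; an ordinary least-squares line (with
intercept, which absorbs the static localization-error offset) gives
`D = slope/(2d)`, floored at zero. Windows in which any of the first five
lags has no observed pair (excitation gaps) are left unclassified and
excluded from state fractions.

Classification thresholds are 0.01 µm²/s (immobile-control ceiling; below
it a window is *non-diffusive*) and 0.04 µm²/s (*low* below, *high* at or
above — the boundary value is assigned upward, since the source rules quote
both strict and non-strict inequalities at 0.04; this is configurable).
State labels are computed on positions smoothed by a centered moving
average (span 5, shrinking symmetric end windows) while D values themselves
are always estimated on raw positions; with noise-free input the smoothing
pass can be disabled (`smooth_span=1`), since its only role is suppressing
noise-induced state flicker. Maximal equal-label runs form segments, and
runs shorter than 10 windows are dissolved into the longer flanking
segment (ties to the earlier one); if every run is sub-threshold the track
collapses to its modal label with a warning.

A consequence of the 20-frame window worth noting: constant drift at speed
v yields an apparent `D = 3 v² Δt`, so directed motion at 300 bp/s
(9.6×10⁻² µm/s) reads ~1.2×10⁻³ µm²/s — an order of magnitude below the
immobile threshold. Slow translocation is therefore *by construction*
pooled into the non-diffusive class, which is why processive events are
detected by the separate long-range segmentation below.

Localization precision is reported as σ₀ = s/√N from the Gaussian-fit SD
s and photon count N (the standard shot-noise relation).

## Dwell-time analysis

Event durations are modeled as exponential mixtures. The one-component MLE
is the sample mean (with right censoring: total observed time divided by
the number of uncensored events). The two-component fit runs EM from five
deterministic starts (a median quantile split plus log-spaced tau ratios)
to a 10⁻⁸ log-likelihood tolerance; with censored events the same starts
seed a direct Nelder–Mead optimization of the censored likelihood.
Components are reported slow-first; weights below 0.01 are flagged
degenerate. Model selection minimizes AIC = 2k − 2logL with k = 2c − 1
free parameters for c components; ties go to fewer parameters.

Reporting convention: the fitted time constants τ are reported as the
primary "half-life" field, matching how such fits are commonly labeled in
this assay's literature; ln(2)·τ is additionally emitted, clearly named.
All recovery validation is convention-independent (simulate at θ, recover
θ). Censoring is off by default; the Kaplan–Meier path exists for survival
curves (via lifelines) and for quantifying photobleaching bias on synthetic
data. Durations below one frame time are excluded by default, since the
line time bounds detection.

## Two-color colocalization

For a molecule pair with mean diffusion coefficients D₁, D₂, the expected
per-frame displacement scale of molecule i under independent Brownian
motion is xᵢ = √(2DᵢΔt), and the colocalization threshold is d = x₁ + x₂
(for D₁ = D₂ = 0.04 µm²/s at Δt = 42.4 ms, d ≈ 0.117 µm). An empirically
determined constant threshold can be imposed instead. Trajectories are
Gaussian-smoothed over a 5-exposure window (σ = 1.25 frames, truncated at
the window) before the per-frame separation test; maximal sub-threshold
runs are candidate events. A wider kernel was rejected because it smears
single-frame contacts beyond any threshold, erasing exactly the short
recoil class the analysis exists to count.

Classification: runs longer than 5 exposures are long colocalizations.
Shorter runs pass through two tests in order, computed on the *raw*
separation so smoothing does not deflate displacements: (1) if the
separation displacement across the run exceeds the model displacement d,
the event is long; (2) otherwise, if the apparent diffusion coefficient of
the separation over the run plus two frames of context exceeds the
per-molecule mean D, the contact was a fast graze — short; else long.
(The separation of two independent diffusers moves with D₁+D₂, twice the
per-molecule mean, while co-diffusing pairs hold a nearly constant
separation — that contrast is what the test exploits.) Bypass takes
precedence over both: a run is a bypass when the sign of x₁−x₂ averaged
over 5 smoothed frames before vs. after the run flips and both tracks
persist ≥ 5 frames on each side.

Nucleosome maps: green-channel signals are piecewise-constant positions
held from the last visible signal across pulsed-excitation dark gaps and
after photobleaching. Signals whose observed positional SD exceeds twice
the localization precision (0.144 µm default) are excluded as unstable
(non-specific adsorption), and exclusion propagates through linked signals.
Remodeler–nucleosome colocalization uses a 500 bp radius through the
configured µm/bp constant.

## Translocation

Constant-speed intervals are found by exact penalized changepoint
segmentation: a dynamic program over per-segment OLS-line residual sums of
squares (O(1) per candidate segment via prefix sums, O(n²) overall) with a
BIC-like penalty 4σ̂²ln n, σ̂ estimated robustly from first differences
(MAD-based, insensitive to the trend itself). A manual-changepoints path
accepts hand-drawn boundaries. Each segment's OLS slope converts to bp/s;
admission requires ≥ 300 bp span, ≥ 5 s duration and R² ≥ 0.5 — filters
chosen so that no-hydrolysis (ATPγS-like) static colocalization traces
yield zero admitted segments, which the validation suite confirms on 100
noisy controls. Note the joint implication of the filters: at one pixel of
noise a 20 bp/s event needs ~40 s before its R² clears 0.5, and ~29 bp/s
needs ~20 s; short slow events are deliberately unreportable.

Trace fragmentation labels every frame translocating (inside an admitted
segment), engaged-static (nucleosome-colocalized), or 1D search, in that
precedence; label runs shorter than 5 frames — localization-noise flicker
across the colocalization radius — are dissolved into the longer flank.
The push–pull call compares the translocation direction with the approach
direction, read as the OLS slope sign of smoothed positions over the final
20 observed frames (~0.85 s, the same span as the diffusion window) of the
search segment adjacent to the translocation, directly or across one
engaged segment. When the search segment follows the translocation
(disengagement), the initial frames are used and the sign inverted. A
5-frame read was tried first and rejected: at one pixel of noise and a
realistic ~0.35 µm/s approach its SNR is ~1, making ~30% of sign reads
wrong; 20 frames brings the error below 2%.

## Force-clamp nucleosome counting

Under a 15–20 pN clamp each nucleosome's inner DNA turn releases as a
discrete ~25 nm extension step. The distance signal is segmented into
constant levels by the same exact DP (constant-mean costs, penalty
6σ̂²ln n); changepoints closer than 4 samples are merged, since they
describe one burst of coincident unwrapping, and levels are taken as
segment medians so a just-unresolved intermediate level cannot bias its
neighbours. Level increases ≥ half the expected step are steps; a jump
≥ 1.75× the expected step is counted as the nearest integer multiple of
25 nm (coincident events) and flagged. Baseline drift exceeding one step
over the trace triggers a warning.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume —
it is the ground truth for every validation:

- state-switching 1D Brownian motion (continuous-time Markov chain over
  non/low/high D levels; reflecting tether ends; per-frame Gaussian
  localization noise whose differenced variance 2σ² adds to 2DΔt);
- exponential and exponential-mixture dwell draws;
- two-color encounters: the pair separation is built around a contact —
  time-reversed and forward unconstrained walks for the flanks, so the
  threshold band is crossed at genuinely diffusive speed. *Recoil* adds a
  prompt drifted entry/bounce (3 µm/s default, comparable to a
  high-diffusive molecule's per-frame RMS excursion) modeling a collision
  that is entered and left within a couple of frames; *co-diffusion*
  freezes the separation (shared displacement applied to both particles,
  independent per-channel noise) for an exponential dwell; *bypass* swaps
  the particles' sides after contact;
- piecewise-linear translocation at set bp/s speeds, optionally with a
  co-moving nucleosome channel, and a composed
  search → engage → translocate story (4 s biased-diffusive approach at
  0.35 µm/s — under the 5 s admission filter so an approach can never be
  admitted as translocation — 3 s static engagement, 33 s translocation
  at 29 bp/s) for push/pull validation;
- force-clamp traces with exponential waiting times (0.5/s default)
  between 25 nm steps at 2 nm distance noise, sampled at 20 ms;
- an observation model applying pulsed-excitation dark gaps and
  single-step exponential photobleaching.

Everything is driven by `numpy` Generators derived from one user seed via
`SeedSequence` spawn keys per named stream, so outputs are bit-reproducible
and adding a pipeline stage never shifts another stage's randomness.

**What passing recovery does not show.** The generator draws idealized
Gaussian localization errors, memoryless state switching, piecewise-ideal
translocation and instantaneous unwrapping steps. Real kymographs add
sequence-dependent affinity structure, intensity-dependent localization
error, fluorophore blinking, tracking artifacts at crossings, and drift.
Recovery on synthetic data certifies that the estimators are correctly
implemented and unbiased under their own assumptions at the published
operating points — not that those assumptions hold for any given
instrument.

## Validation sizes and tolerances

The test suite recovers: diffusion classes at D ∈ {0.005, 0.02, 0.05}
µm²/s (50 tracks × 5000 frames each, ≥ 90% modal accuracy); exponential
lifetimes across 0.7–20 s (n = 1000, 3 SE); mixture components 18/2 s and
12/2 s (n = 2000, 10%); translocation speed 29 bp/s over 100 noisy 33 s
traces (5%); short/long encounter classification at 0.033 s vs 0.70 s
dwells (≥ 90% per class); bypass on 100 constructed crossings (100%) and
100 recoil geometries (0%); nucleosome counts at 10 and 30 per array
(≥ 95% exact over 100 runs each); and push/pull calls on 200 composed
traces (≥ 95%). MSD/rolling-D implementations are additionally pinned to a
brute-force oracle at 10⁻¹⁰ relative tolerance. Problem sizes were chosen
so the full suite runs in about a minute on one CPU while leaving each
statistical bound several standard errors of headroom.
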