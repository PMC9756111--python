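# Methods

This note documents the statistical models, numerical choices, and known
limitations of each analysis stage, and what the synthetic-data
generators do and do not emulate.

## Dwell-time analysis (`survival`)

Binding lifetimes of single complexes are right-censored by the finite
recording window (typically ~10 min) and by photobleaching. The survival
function is estimated with the Kaplan–Meier product-limit estimator
(computed via `lifelines`); censored molecules leave the risk set
without stepping the curve, and tied event times form one combined step.
Pointwise confidence bands come from a case bootstrap: molecules —
(duration, censored) pairs — are resampled with replacement, never time
points, and percentile intervals are taken per grid time (default level
0.68, matching the 1-σ convention of single-molecule work).

The two-population mixture S(t) = (1−f)·e^(−t/τs) + f·e^(−t/τl) is
fitted by default to the censored-data likelihood (events contribute the
density, censored observations the survival), which uses the censoring
information correctly; a least-squares fit to the KM step values is kept
as a compatibility mode and agrees with the MLE on clean data.
Label switching is resolved by relabeling so τs ≤ τl at construction.
Optimization is Nelder–Mead on (logit f, log τs, log τl) with a
method-of-moments start (split at the median lifetime) plus 10 random
restarts; non-convergence is flagged in the result, never silent.
Standard errors come from a central-difference Hessian at the optimum,
delta-transformed to the natural scale; they are asymptotic and should
be treated as indicative for n below a few hundred events.

## Diffusion (`tracking`)

Puncta are localized by nonlinear least squares with a symmetric
Gaussian plus constant background (2D for image windows, 1D per kymogram
scan line, selected by dimensionality); the center uncertainty is taken
from the Jacobian-based fit covariance. Fits with amplitude at the noise
level, or failed fits, are flagged invalid rather than raising, so batch
pipelines can skip bad frames. Quality filtering (maximum uncertainty,
minimum amplitude — defaults are deliberately permissive and
config-exposed, since discard thresholds are instrument-specific)
removes frames while preserving time stamps, and the diffusion estimator
never forms an increment across such a gap.

Per-complex diffusion coefficients use the covariance-based estimator
for uniformly sampled tracks without motion blur:

    D̂ = ⟨Δx²⟩/(2Δt) + ⟨Δxₙ·Δxₙ₊₁⟩/Δt,   σ̂² = −⟨Δxₙ·Δxₙ₊₁⟩.

Localization noise inflates the increment variance by 2σ² and creates a
lag-1 increment covariance of exactly −σ²; the second term cancels the
first's bias, so E[D̂] = D, and D̂ may legitimately come out slightly
negative for static molecules. The estimator variance is evaluated with
the standard formula var(D̂) = D²[(6+4ε+2ε²)/n + 4(1+ε)²/n²], ε =
σ²/(DΔt), at the estimated values. Ensemble MSD fitting is deliberately
not provided: estimates are per complex.

Mobility classification replaces by-eye kymogram reading with an
explicit rule: a track is "mobile" iff D̂ exceeds a threshold (default
0.005 µm²/s) by more than twice its standard error. On simulated tracks
(500 frames, 30 nm localization noise) this gives ≥95% specificity for
static molecules and ≥90% sensitivity at D = 0.05 µm²/s.

## Photobleaching step counting (`stepfind`)

Traces of puncta containing several identical fluorophores are fitted
with a piecewise-constant model found by greedy changepoint insertion
under a BIC-type criterion (AIC selectable). In constrained mode the
segment levels are snapped to the lattice {baseline + k·f, k ≥ 0} of the
single-fluorophore intensity f, which encodes the constant-step-size
constraint; the parameter count is then k changepoints + 1 noise
variance (+1 when f is profiled), against 2k+2 for free levels, so on
lattice-true data the constrained fit wins the model comparison.
Up-steps are permitted (fluorophore blinking recovers reversibly;
bleaching is irreversible). Two numerical safeguards matter at low
signal-to-noise: a fitted level must persist ≥2 frames (single-frame
excursions are indistinguishable from noise spikes), and because greedy
insertion with snapped levels cannot carve out a short dip in one move
(the intermediate level rounds away), changepoint candidates are pooled
from constrained *and* unconstrained forward passes and then pruned by
backward elimination under the constrained criterion.

When f is unknown it is profiled over 50 log-spaced candidates between
0.6× the median unconstrained step size and the trace maximum, refined
by bounded 1D minimization; among near-optimal candidates the largest is
taken, because on lattice data f/2, f/3, … fit exactly as well and only
the largest is the physical unit. Across traces, f is estimated from the
pooled step-magnitude histogram with a two-component Gaussian mixture
whose means are constrained to f and 2f (widths σ and σ√2), so
double-bleach events do not bias the unit.

Captured-oligo counts are N = round(F(0)/f) with F(0) the *fitted* level
of the segment containing the flush reference frame (robust to
single-frame noise, unlike the raw first sample); ties round half-up and
counts are capped (default 20) with a warning. On simulated traces the
step count is recovered in ≥90% of traces at unit/noise ratio 3 and N is
exact in ≥95% at ratio 5.

## Dual-color stoichiometry (`oligomer`)

A cluster of N labelable units acquires c cyan and m magenta labels
with trinomial probability f(c,m; N, p_c, p_m), parameterized by the
overall labeling efficiency κ = p_c + p_m and asymmetry γ = p_c/p_m.
Closed forms are used throughout (∑_{c≥1} f(c,0) = (p_c+q)^N − q^N with
q = 1−κ; α = 1 − q^N), verified in tests against exhaustive enumeration.
Observed categories (cyan-only, magenta-only, dual) are conditioned on
detection. For a cluster-size distribution φ(N; μ) — point mass, or
zero-truncated Poisson φ(N) = μ^N e^(−μ)/(N!(1−e^(−μ))) — the detected
population is φ(N)α(N)-weighted, so the mixture category probabilities
are computed as ∑φ(N)f_i(N) / ∑φ(N)α(N); at κ = 1 (the default,
reflecting the working assumption of no unlabeled complexes) this
coincides with the plain φ-weighted mixture of conditional
probabilities.

Inference maximizes the multinomial log-likelihood of the three category
counts: over integers N = 1..12 for the fixed-size model, over
continuous μ (grid scan plus bounded refinement) for the truncated
Poisson, whose sum over N is truncated adaptively so the neglected tail
is <1e−10. The reported "average cluster size" is the mean of the fitted
distribution — μ/(1−e^(−μ)) for the truncated Poisson, which exceeds the
Poisson parameter itself; both are returned. Boundary maxima are
flagged. γ can be estimated by matching the observed single-color ratio
(root finding) or by joint MLE; a sensitivity table over a γ grid makes
explicit that the size estimate depends only weakly on γ. Because
unlabeled complexes are invisible, decreasing κ in the model never
decreases the size estimate: all sizes at κ = 1 are lower limits, and
the fit report says so.

## Fork-tract mechanics (`polymer`)

The worm-like-chain interpolation formula
F(ξ,L,p) = (k_BT/p)[¼(1−ξ/L)⁻² − ¼ + ξ/L] relates force, end-to-end
extension, contour length and persistence length. Defaults: p = 1.4 nm
(midpoint of the 1.3–1.5 nm range reported for RPA-coated ssDNA) and
k_BT = 4.11 pN·nm (~25 °C). The inversion for L is a bracketed Brent
root find on L ∈ (ξ, 10³ξ] — unique because force is strictly decreasing
in L at fixed ξ — and round-trips to six digits. The interpolation
formula itself is a few-percent approximation to the exact WLC, and no
stretch modulus is included, so contour lengths at ≥65 pN carry that
systematic uncertainty; since the same model maps every frame, *changes*
in L (sliding, reannealing) are far more reliable than absolute values.

Tract edges are found per scan line by thresholding at background + 0.5
× (plateau − background) with sub-pixel linear interpolation at the
crossings — for a Gaussian-blurred step the half-amplitude crossing sits
exactly at the true edge, which makes this threshold unbiased under PSF
broadening. For kymogram series the image is boxcar-smoothed 3 frames ×
3 px, but only within runs of constant force: the extension jumps at
force steps and smoothing across a jump smears the edges. Background and
plateau are calibrated in two passes (rough percentile split, then
medians of the two sides). Frames with force below 1 pN are masked — the
WLC inversion is ill-conditioned at low tension, where wide ranges of L
produce nearly identical extension. On rendered kymograms with a
constant 3 µm contour under a 5↔65 pN protocol the recovered L(t) stays
within 5% of truth frame by frame.

## Event statistics (`quantify`)

Binding events are classified junction if within 300 nm (~diffraction
limit) of the nearest tract edge, else ssDNA inside a tract, else dsDNA
— exhaustive and mutually exclusive. Substrate availability assigns each
tract edge a junction band of width 2 × 300 nm (the window on both
sides), clipped to the tether and merged on overlap, subtracted from the
flanking classes so availabilities sum to exactly 1. This band
definition is our choice — a peak-distance classification rule does not
by itself define junction "available length" — and the junction
enrichment value depends on it directly, so it is the first thing to
revisit when comparing across studies. Enrichment is log2E = log2 x −
log2 a per class; zero-count classes are reported −∞ and flagged.

Fisher's exact test (via scipy) uses the two-sided minimum-likelihood
convention: the p-value sums hypergeometric probabilities of all tables
with the observed margins no more likely than the observed one; tests
verify exact agreement with full-table enumeration. Protection fractions
(tracts retaining their RPA signal at low force, per number of occupied
termini) carry 68% percentile case-bootstrap intervals, which collapse
one-sidedly at 0/n and n/n. Compaction rates use a Theil–Sen slope over
the monotone interval between the (lightly smoothed) maximum and
subsequent minimum length, robust to localization outliers.

## Synthetic data (`simgen`)

One root seed spawns fixed per-generator child streams, so every
generator is a pure function of (parameters, seed) and adding a
generator never perturbs another's draws. What is emulated, and what is
not:

* **Lifetimes** — exact mixture draws with deterministic right-censoring
  at the window end. No photobleaching-limited censoring distribution.
* **Tracks** — Brownian increments N(0, 2DΔt) plus i.i.d. Gaussian
  localization noise; exactly the CVE's assumed model. No motion blur,
  confinement, or tether fluctuations.
* **Bleaching traces** — per-fluorophore discrete-time Markov chain:
  irreversible bleaching from the emitting state (per-frame probability
  1−e^(−rΔt)), optional two-state blinking telegraph (off by default —
  blinking is a nuisance, not a signal), additive Gaussian camera noise,
  F(t) = f × n_emitting(t). No shot-noise scaling with intensity by
  default and no Qdot power-law blinking; no magnitudes are claimed as
  measured values, they are config-exposed.
* **Label counts** — sizes from φ, labels trinomial via sequential
  binomials, unlabeled clusters discarded as undetected.
* **Kymograms** — tracts as top-hats analytically convolved with the
  Gaussian PSF (erf profile), puncta as Gaussians, additive Gaussian
  noise, out-of-field content clipped with a warning. No TIRF
  illumination profile, bilayer drift, or camera EM gain statistics.
* **WLC traces** — forward extension at (L(t), F(t)) plus noise, with
  the true contour retained for round-trip checks.

Ground truth (true N, D, bleach frames, tract edges, punctum positions)
always rides along, so every recovery test compares against the
generator's record, not a reimplementation. Consequently, passing tests
demonstrate correctness of the estimators *under their assumed models*
and calibrated behavior at realistic noise levels; they do not cover
instrument systematics absent from the generators (drift, uneven
illumination, non-Gaussian noise tails).

## Problem sizes used in the shipped checks

Recovery suites use 100 simulated datasets at the n≈141-event scale for
cluster-size fits, 5000 censored draws for the double-exponential fit,
500 tracks × 1000 frames for CVE bias, 100 traces for step-count
recovery, and 200-frame kymograms for the end-to-end tract pipeline —
sizes at which the asymptotic tolerances quoted above are meaningful
while the whole suite stays desk-scale.
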