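# Methods

`phasestates` is a synthetic benchmark for brain-state inference: it
generates EEG-like sessions in which the ground truth is a sequence of
transient phase-coupling networks, runs them through a controlled
forward/inverse chain, and scores how well Gaussian and time-delay
embedded hidden Markov models (TDE-HMMs) recover the hidden states.
This note documents the generative model, the inference machinery, the
numerical choices, and — importantly — what the benchmark can and cannot
show.

## Generative model

**Sources.** Each of P cortical sources is a band-limited alpha
oscillation: a sum of sinusoids on a dense grid across 10 ± 2 Hz
(0.01 Hz spacing), each sinusoid with an independent Uniform(0,1)
amplitude and Uniform(0,2π) phase, smoothed by a fifth-order all-pole
filter and rescaled to unit variance. The filter places a conjugate
pole pair at radius 0.95 at the band-center digital frequency and the
remaining poles at 0.1 on the real axis; this shapes the alpha peak
without moving power outside the band (the sinusoid grid already
confines it), and makes the construction fully reproducible. No warm-up
samples are discarded; at session length the transient is negligible.
Sessions are 125 Hz throughout.

**States.** Hidden states follow a semi-Markov chain: the embedded
transition matrix has flat-Dirichlet rows with the diagonal forced to
zero (dwell time is drawn explicitly, so self-transitions would
double-count persistence), and each occurrence's dwell time is
Uniform(duration range) in milliseconds, rounded half-up to samples.
Each state owns a random set of directed coupling edges
(driver → target, target phase difference Δφ ~ Uniform[−π, π)). A
source may be the target of at most one edge per state — otherwise two
edges could demand contradictory phases from the same target — which
caps the edge count at P − 1; requested ranges above the cap (the dense
condition) are clipped with a logged warning. Drivers are drawn
uniformly among the other sources, so chains (a rewritten source acting
as a driver through its *original* phase) are allowed.

**Coupling injection.** During each occurrence of state k, every edge
(i → j, Δφ) rewrites the target as
y_j(t) = A_j(t)·cos(θ_i(t) + Δφ + ε), where A_j is the target's own
Hilbert envelope, θ_i the driver's original instantaneous phase, and
ε ~ N(0, std-pd²) is drawn once per occurrence and edge. Amplitudes are
therefore preserved exactly by construction; only phase carries state
information. Envelope and phase are computed once from the full
original session (Hilbert transform inside short occurrences would
suffer edge artifacts). Occurrence boundaries introduce waveform
discontinuities; no cross-fade is applied, and this is a known artifact
of the construction.

**Forward model.** An analytic three-concentric-spheres conductor
(brain/skull/scalp radii 0.087/0.092/0.100 m, conductivities
0.33/0.0042/0.33 S/m) replaces anatomical head models; the potential of
a radial unit dipole is a truncated Legendre series (60 terms; the
per-order coefficients solve the 5×5 boundary-condition system for the
three shells, and the homogeneous limit reproduces the classical
single-sphere series). Sensors are a golden-angle lattice on the scalp;
sources sit at 0.082 m — superficial, like cortical generators. Deeper
placements give very smooth topographies (90% of lead-field energy in
~8 of 78 spatial dimensions) and unrealistically severe leakage. The
lead field is average-referenced. A user-supplied lead-field matrix can
replace the built-in model.

**Noise and SNR.** Sensor noise is zero-mean Gaussian, i.i.d. over
time, with covariance L·Lᵀ + Λ: the first term is spatially structured
"biological" noise that shares the head model's mixing, the second is
instrumental noise with Λ_ii = 0.1 × var(signal_i) per sensor. The
noise is scaled by γ = sqrt(var(signal)/(var(noise)·10^(SNR/10))),
variances pooled over sensors and samples, so the achieved SNR is exact
by construction.

**Inverse chain.** An array-gain LCMV beamformer (unit-norm lead-field
columns, covariance regularized by 5% of the average sensor power on
the diagonal) reconstructs activity at the true source locations;
parcels are therefore single-location and the first-PC parcel reduction
is exercised separately by its own tests. Leakage correction is
innovations orthogonalization: fit a VAR(5) to the parcel courses,
whiten the innovation *correlation* matrix with a symmetric (ZCA-style)
inverse square root — correlation, not covariance, so uncorrelated but
unequal-variance innovations pass through unchanged — and re-filter the
whitened innovations through the fitted VAR. Two numerical guards
matter in practice: the innovation correlation of beamformed data can
be nearly rank-deficient, so eigenvalues are floored at 0.05 before
inversion (directions above the floor are whitened exactly); and the
least-squares VAR on narrowband data can be marginally unstable, so the
companion-matrix spectral radius is shrunk to 0.999 before re-filtering.

## Inference

Both models share one recipe: z-score each parcel course, optionally
stack lags −1, 0, +1 (time-delay embedding; source-major, lag-minor row
order), project onto the smallest set of principal components explaining
60% of variance, fit a zero-mean full-covariance Gaussian HMM, and
Viterbi-decode (log-domain, ties toward the lower state index).
Zero-mean emissions make each state a pure covariance pattern; the
embedded model's covariance spans lags and is therefore sensitive to
phase and spectral structure, while the Gaussian path sees only
instantaneous covariance. K = 10 states, matching the generative truth,
is fixed rather than selected.

**Fitting.** Parameters are estimated by Baum–Welch EM (hmmlearn
underneath, subclassed to keep emission means pinned at zero) with
convergence at relative log-likelihood improvement < 1e-6 or 500
iterations, a weak inverse-Wishart-style covariance prior (1e-2·I
pseudocounts) that keeps the M-step positive definite when a state
starves, and 5 restarts selected by final log-likelihood.

**Why restarts are not enough, and what replaces them.** The
log-likelihood surface of covariance-switching HMMs on this data class
is glassy: from random initializations EM reliably freezes into
"shattered" solutions whose states are temporal fragments blending
several true coupling patterns (these are not amplitude states — their
mean power is flat). Seeding EM at the ground-truth configuration shows
the truth basin is the global optimum at the benchmark's scale, but its
basin is effectively unreachable by random restarts, annealing,
stickiness priors, or covariance-feature clustering (all were tried).
The first restart is therefore initialized from a phase-informed
segmentation (`segmentation` module): smoothed pairwise
phase-difference phasors of the most state-dependent channel pairs,
changepoint detection that deliberately over-segments, and bottom-up
Ward merging of length-weighted segment phasor patterns down to K
clusters. Segments enter clusters wholesale, so shattered
configurations are excluded from that starting point by construction.
The remaining restarts stay random, and selection is still by
likelihood, so the informed start competes rather than dictates.

**Scoring.** Inferred labels are aligned to ground truth by the
Hungarian (Munkres) assignment on indicator correlations (truth cropped
by the embedding's left lag span), and recovery is the mean per-state
Pearson correlation between matched binary indicator courses; states
never visited contribute r = 0 (logged) so means stay comparable.
Condition effects use one-way Welch heteroscedastic ANOVA over the 18
factorial cells and Games-Howell post-hoc comparisons at α = 0.01 with
99% confidence intervals (studentized-range based; half-width
q/√2 × SE).

## Scales and runtime

The `full` profile is the original study's scale (78 sources, 10
states, 5-minute sessions, 126 sensors). The bundled analyses and
tests use the `desk` profile: identical source space, state count, and
montage, with sessions shortened to 60 s. Source count cannot be
scaled down: with the PCA budget fixed at 60%, the embedded space of 20
sources keeps only ~12 dimensions, and even an EM fit seeded at the
ground truth relaxes away from it — the maximum-likelihood optimum at
that scale is simply not the truth. The `tiny` profile (6 sources, 3
states, 20 s) exists to smoke-test the full chain in seconds, not to
recover states; at 6 sources the 60% cut keeps 4 dimensions and no
optimizer can reach high recovery there. Acceptance-level tests run
1–2 repetitions per condition and 2 EM restarts (the informed restart
plus one random competitor); the acceptance script runs the full 5 × 3
grid with 5 restarts.

## What passing (and failing) shows

The oracle suite pins every primitive to an independent reference:
Viterbi against exhaustive path enumeration, Hungarian matching against
all 5! permutations, the embedding against hand-shifted matrices, the
SNR scaling against its closed form, EM monotonicity on every fit, the
spherical lead field against the homogeneous-sphere series and its own
truncation convergence, and the jitter machinery against circular
statistics. One caveat discovered on the way: Welch's F does **not**
equal the classical one-way F under exactly equal variances in finite
samples — Welch's denominator 1 + 2(k−2)/(k²−1)·Λ exceeds one — so the
equivalence is asserted in its exact finite-sample form.

On recovery levels, the benchmark is honest about a gap. At the desk
scale the TDE-HMM recovers states well above chance and above the
Gaussian HMM, but the headline ≥ 0.9 matched correlation at 10 dB is
not reached through the sensor chain: beamformer leakage blurs the
pairwise-phase structure that the informed initialization needs, and at
60-s sessions the likelihood optimum on leakage-corrected data is not
the ground-truth configuration at all (it becomes the optimum again at
≥ 150-s sessions, but remains unreachable by truth-blind search).
Recovery through the chain therefore plateaus around 0.2–0.3, versus
0.6–0.8 on source-level data and ~0.99 for truth-seeded fits at the
full 78-source scale. Passing tests show the machinery is correct and
the directional model contrast is real; they do not show that
variational-quality state recovery through a realistic inverse chain
has been reproduced.

## Known limitations

- Single alpha band, no 1/f background, no amplitude coupling, no
  artifact (ocular/muscular) noise: the structured-Gaussian noise model
  is the only non-signal source.
- Radial-only dipoles on a single eccentricity shell; no realistic
  BEM/FEM geometry.
- The inference engine is exact EM with restarts, not stochastic
  variational inference; the phase-informed initialization compensates
  on source-level data but not through the inverse chain (see above).
- Occurrence-boundary discontinuities are left in the signals by
  design.
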