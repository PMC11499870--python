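# Methods

This note documents the models and estimators implemented in driftsteer,
the calibration of the network's free parameters, the numerical choices,
and what the synthetic-data tests do and do not establish about real data.

## Orientation-tuning estimation

**ΔF/F.** The fluorescence of a neuron is corrected for neuropil
contamination with a fixed coefficient of 0.7,
`F(t) − 0.7·(F_np(t) − median(F_np))`, and converted to a fractional
change about the median of the corrected trace over all 1 s pre-stimulus
windows.  A non-positive baseline median raises an error rather than
producing unbounded values.

**Responsiveness.** Per direction, stimulus-window means are compared to
pre-stimulus-window means with a two-sample Mann–Whitney rank-sum test
(normal approximation, tie correction) at a Bonferroni-corrected level
α/n_stim; the stimulus median must also exceed the pre-stimulus median, so
suppressed neurons never count as responsive.

**Vector-sum PO.** Orientation lives on a 180°-periodic circle, so all
angles are doubled before averaging.  The PO is half the angle of the
response-weighted resultant of `exp(2iθ)` over every direction ×
repetition entry, computed with the two-argument arctangent (a plain
`arctan(Y/X)` loses the quadrant).  A resultant below 1e-9 times the mean
absolute response is declared undefined (e.g. perfectly uniform
responses); callers treat such neurons as untuned.  The estimator is
exactly invariant to scaling all responses, exactly equivariant to
rotating the stimulus directions, and exact at orientations aligned with
the direction grid.  Off-grid, sampling a smooth tuning curve at 6
distinct orientations leaves a harmonic-aliasing bias which is < 0.05°
for typical widths (~25° Gaussian σ) and grows for very narrow curves;
this is visible in the noiseless tests as a worst-case error of ~1° and
is inherent to the 12-direction design, not to the estimator.

**Bootstrap CI.** Repetitions are resampled with replacement and the PO
recomputed per resample.  The point estimate is the circular mean of the
bootstrap distribution; the 95% CI takes the 2.5th/97.5th percentiles of
the bootstrap angles after centering on that mean in doubled-angle space,
which avoids branch-cut artifacts near ±90°.  A neuron whose full CI
width exceeds 90° (half-width 45°) is untuned for that session.  Two
resampling schemes are provided.  *Per-direction* (default): repetition
indices drawn independently for each direction; because single-trial
responses are independent, this uses all n_stim·n_rep degrees of freedom
and measures ~94% coverage of the true PO on synthetic ground truth.
*Joint*: one index set shared across directions — a block bootstrap over
~32 repetition blocks whose percentile intervals are systematically
slightly narrow (~92% measured coverage, the classic small-block
deficit); it remains available for data in which slow state changes make
responses covary within a repetition.  n_boot defaults to 1000.

**Drift statistics.** For every session pair, concurrently tuned neurons
(responsive *and* tuned on both days) get a signed ΔPO in (−90°, 90°], a
drift magnitude |ΔPO| ∈ [0°, 90°], and a significance flag requiring each
day's PO to fall outside the other day's CI (both tested circularly).
Relative to an experienced orientation, rPO = |PO − experienced| ∈ [0°,
90°] and convergence Δ|rPO| = rPO_pre − rPO_post.  Population summaries
are medians with percentile-bootstrap CIs (default 10 000 resamples).

**Shuffle nulls.** Drift direction is binarized as toward/away from the
experienced orientation.  The *magnitude* shuffle permutes |ΔPO| across
neurons keeping directions; the *direction* shuffle assigns random signs
keeping magnitudes.  In both, rPO_post is re-derived as
`clip(rPO_pre − direction·magnitude, 0°, 90°)` and the median convergence
recorded per shuffle.  If convergence reflects a direction bias (not a
magnitude change), the magnitude shuffle leaves it intact and the
direction shuffle centres it on zero — the dissociation the package tests
on both synthetic imaging data and model output.

**PSC decay.** Pairwise signal correlations (Pearson, over 12-point
trial-averaged tuning curves) are vectorized per day (strict upper
triangle), correlated across day pairs, and fitted with
`y = a + b·exp(−c·x)` by bounded least squares (initialized at
`(min y, max y − min y, 0.1)`, c ≥ 0, tolerances 1e-14 so exact data are
recovered to ~1e-8).  Zero-variance tuning curves yield NaN entries that
are dropped pairwise.

**Behavioral filters.** The running (or arousal) modulation of a PO
change is the Pearson correlation between single-trial response
amplitudes and running speed (pupil diameter), multiplied by the mean
across-session change of the covariate; `filter_by_modulation` drops the
most-modulated fraction of records with a deterministic tie-break
(higher neuron ids dropped first).

## The synthetic imaging generator

One seed drives the whole experiment through spawned substreams (schedule,
neuropil, behavior, drift, one per neuron), so outputs are
bit-reproducible and partially regenerable.  Tuning curves are circular
Gaussians (period 180°) with log-normal widths (median 25°, log-sd 0.25);
responses sit on a baseline fluorescence of 100 a.u. with additive
Gaussian frame noise and a shared neuropil trace mixed at the same 0.7
coefficient the analysis removes, making the noiseless round trip exact.
A single AR(1) arousal latent generates correlated running speed and
pupil diameter and multiplies response gain (default ±10%), leaving the
PO untouched by construction.  Ground-truth POs evolve per day as
nothing, a pure random walk (default 2°/day, matching the observed
~0.3°/day median rate over 20-day windows through √t diffusion), or a
biased walk whose mean step is a fixed fraction of the signed distance to
a target orientation — the deprivation-like condition.  The default bias
(0.01/day, with the same 2°/day step noise) reproduces the published
convergence scale (~10° over 28 days) while keeping the walk
noise-dominated, so drift magnitude stays direction-independent as
observed experimentally; stronger pulls make magnitude and direction
covary and break that correspondence.

What it does *not* emulate: calcium indicator kinetics (responses are
rectangular within the stimulus window), correlated noise across neurons,
ROI segmentation or matching errors, bleaching, or state-dependent tuning
changes.  Passing tests therefore certify the estimators under the
generative assumptions (independent trials, PO-preserving gain, Gaussian
noise), not robustness to those artefacts.

## The plasticity network

Two layers of N = 500 neurons.  Presynaptic rates are Gaussian tuning
curves (σ_u, see calibration) over uniformly tiled preferred orientations;
the readout is linear, v = Wᵀu.  Every stimulus updates all weights by
`Δw = ε·tanh(10w)·(k·H + ξ)` with `H_ij = u_j·v_i` and ξ drawn i.i.d. per
weight per stimulus; ε = 1e-4, σ = 1, k ∈ [0, 1].  After each simulated
day (N_θ = 43 200 stimuli = 1/s for 12 waking hours) incoming weights are
divisively normalized to unit sum; the package verifies the sum to 1e-12
after every day.  Weights are clipped at zero after each update: ρ is
negative below zero, which would make volatility self-amplifying there,
and weights represent synaptic strengths.  At the default operating point
the clip is effectively never active (it would require a >10 σ volatility
draw), so near-zero weights evolve multiplicatively and never hit the
absorbing state.  Weight profiles are initialized as 180°-periodic
Gaussians with log-normal widths, giving log-normal-like drift-magnitude
variability across neurons.  POs are read out with frozen weights by
sweeping a stimulus grid (step 180°/N = 0.36°) and taking the argmax,
ties to the smaller angle.

**Protocols.** Baseline draws each stimulus uniformly from [−90°, 90°);
deprivation presents a constant experienced orientation θ̂; interrupted
deprivation opens every period-th day (default 7) with a plastic block of
uniformly drawn stimuli (default a quarter of the day) — measurement
sweeps are always frozen, but interruption exposure must be plastic or it
could not slow convergence.  Every run starts with a 3-day baseline
warm-up before measurement.  Ensembles use seeds `base + i`.

**Calibration.**  ε, σ, ρ and N_θ are fixed; the presynaptic rate scale is
not, and H is homogeneous of degree 2 in it, so a single multiplier pins
the Hebbian/volatility balance.  Balancing the *per-update magnitudes*
(mean |H| = mean |ξ|) is offered as a calibration mode but is not usable
as an operating point: the Hebbian term accumulates coherently over a
day's 43 200 stimuli while volatility only diffuses, so a per-update
match hands H an effective √N_θ ≈ 208-fold advantage and the network
snaps onto the experienced orientation within a day or two.  The default
mode therefore balances *per-day contributions*:
`ε·N_θ·mean|H| = r · ε·σ·√N_θ·√(2/π)` with the dimensionless ratio
r = `hebbian_day_ratio`.  Its default, r = 0.015, together with the
geometry defaults (presynaptic σ_u = 20°, weight-profile widths
log-normal with median 56° and log-sd 0.45, offset = amplitude/10), was
fixed once against two published anchors of the phenomenon: (i) baseline
median PO drift ≈ 0.3°/day over 19–20-day windows — the same quantity the
learning rate was originally tuned to reproduce — and (ii) orientation
deprivation leaving the drift-magnitude distribution essentially
unchanged (within ~10% of baseline at 28 days) while still biasing drift
direction toward θ̂.  r is the largest value satisfying (ii); the widths
and σ_u satisfy (i) given the printed ε and σ.  At this operating point
deprivation produces a gradual median convergence of ~4° over 28 days,
the direction/magnitude shuffle dissociation, and a small positive rank
correlation (~0.1) between initial |rPO| and drift magnitude — all
emergent, not fitted.  Note the broad weight profiles are a model
abstraction: the drift-relevant geometry is the weight profile convolved
with presynaptic tuning, and narrower profiles would require a larger ε
or σ than the published values to reach the observed drift rate.

**Desk scaling.** `rescale_for_desk(config, c)` divides N_θ by c,
multiplies ε by c and divides σ by √c, preserving both the coherent
per-day Hebbian displacement (∝ ε·N_θ) and the per-day volatility
diffusion (∝ ε·σ·√N_θ).  Statistical agreement across factors is
property-tested.  The shipped problem sizes are c = 200 for the
acceptance script (ten-seed ensembles of 23- and 31-day runs in roughly
ten minutes) and c = 300 / ablations at N = 200 in the test suite; these
sizes are the package's default desk configuration and can be lowered to
c = 1 for full-scale runs.  Volatility draws use single-precision
normals (distributionally N(0,1)) feeding a double-precision update;
weights and normalization stay in double precision.

## Numerical and degenerate-input policy

Undefined POs signal rather than silently returning numbers; bootstrap
resamples with undefined POs are counted and a neuron with > 50%
undefined resamples is untuned.  Non-finite weights abort the simulation
(checked after every public plasticity step, and once per day inside the
optimized loop — non-finite values are absorbing, so nothing is lost).
Dead postsynaptic neurons (zero incoming sum) are reported by index.
Spearman correlations on constant inputs are reported as 0 with a
`degenerate` flag instead of NaN.  All angle outputs are wrapped to
[−90°, 90°) and distances to [0°, 90°].

## Known limitations

* The model has no recurrence, no spiking, no receptor biophysics, and a
  linear readout; its "day" is a stimulus count, not wall-clock time.
* Recovery after deprivation is slow and incomplete in this architecture;
  the package exposes a recovery protocol but makes no claim of matching
  experimental recovery speed.
* The 12-direction design limits PO accuracy for very narrowly tuned
  neurons (aliasing, above); real experiments share this limit.
* Behavioral covariates are a single latent; real running/pupil dynamics
  are richer, so the modulation filters are validated only for gain-type
  confounds.
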