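# Methods

`corticothal` implements a pre-stimulus phase-analysis pipeline for paired
cortical/thalamic recordings — phase bifurcation, inter-site phase clustering,
directed phase-slope connectivity, and single-trial phase-distance mediation —
together with the synthetic generator used to validate it. This note documents
the models, the numerical choices, and what the synthetic validation does and
does not establish.

## Statistics

**Inter-trial phase clustering (ITPC / phase-locking value).** For per-trial
phase angles k_r at a fixed (frequency, time) cell,
`ITPC = |n^-1 Σ_r exp(i k_r)|` ∈ [0, 1]. Rotation-invariant; equals 1 for a
single trial.

**Phase bifurcation index (PBI).**
`PBI = (ITPC_hits − ITPC_combined) · (ITPC_misses − ITPC_combined)`, with
ITPC_combined computed on the union of the two trial sets. PBI is positive
when hits and misses each cluster, at different angles; a single clustered
condition against a uniform one drives it negative. PBI inherits a trial-count
bias (fewer trials inflate ITPC), so it is never interpreted raw: inference is
against a circular-shift surrogate (below). Note that with unbalanced
conditions (e.g. ~71% hits) ITPC_combined stays well above zero even under
perfect antipodal bifurcation, so the attainable PBI is bounded below 1.

**Circular-shift surrogate.** Each permutation rolls every trial's time
series independently by a uniform random number of samples in
[1, n_samples − 1], preserving each trial's autocorrelation and the hit/miss
imbalance while destroying stimulus-locked phase. The observed statistic is
z-scored by the surrogate mean and SD. Two modes:

* *faithful* (default of `pbi_map`): shift the raw signal, re-run the wavelet
  transform per permutation;
* *fast* (used by the pipeline and most tests): rotate each trial's complex
  coefficients by `exp(−i 2π f s/fs)` for a random source-sample shift `s` —
  the effect a circular time shift has on a narrowband analytic signal.
  Shifts are drawn at source-sample resolution deliberately: shifting the
  coarse 50 ms coefficient grid would rotate 10 Hz phase by exact multiples
  of π and produce a degenerate two-point null.

The surrogate also records the one-sided empirical percentile `p_perm`. The
z map is the right object to pool across units (the group test applies a t
across units, where the central limit theorem does the work), but for a
*single* unit the z is a standardized draw from a product-of-near-normals
distribution, not a normal one, so fixed ±1.96 cutoffs are not exactly 5%
tests; single-unit calibration claims are made on `p_perm`, which is uniform
under the null by construction. Cells whose surrogate SD falls below 1e−12
are flagged and carry NaN z rather than an inflated value.

**Inter-site phase clustering (ISPC).** ITPC applied to the per-trial
circular phase difference between two channels; surrogate = shuffling one
channel's trial order (1000 permutations by default). The group lag summary
takes each unit's circular mean lag and averages the *angles* across units
unweighted — a tightly and a loosely clustered unit count equally. Lags
clustering at 0 or π would indicate volume conduction; the planted 20 ms lag
at 10 Hz sits at 2π·10·0.02 ≈ 1.26 rad, far from both.

**Phase slope index (PSI).** From Hanning-tapered per-trial FFTs of the
pre-stimulus window (−800..0 ms, one taper over the whole window, 1.25 Hz
resolution, trials as spectral observations), complex coherency C(f) is
estimated with the standard auto-spectral normalization (no regularization;
degenerate auto-spectra propagate NaN), and
`ψ = Im Σ_{f∈band} C*(f) C(f+δf)` summed over a 6 Hz band (default 5–11 Hz,
centred on the ~8 Hz coupling peak; band edges configurable since no single
placement is canonical). Positive ψ means the first channel temporally
leads. The arithmetic is carried in explicit real/imaginary components so
that `ψ(a,b) = −ψ(b,a)` holds to the bit and identical channels give exactly
zero (native complex multiplication is not conjugate-symmetric at the last
ulp). Inference: trial-shuffle surrogate, 200 permutations. A zero-lag
(volume-conducted) copy contributes nothing, which is why PSI complements
ISPC.

**Hit/miss contrasts under subsampling.** Condition contrasts (ISPC or PSI)
subsample the larger condition to the smaller one's trial count (25 draws by
default, metric averaged over draws) before differencing, removing the
trial-count bias from the comparison. An optional outcome-label permutation
null provides per-unit inference for the contrast.

**Single-trial mediation.** At the PBI-peak cell of each region (argmax of
the unit's PBI z inside the pre-stimulus 6–14 Hz region of interest), the
per-trial predictor is the distance to the optimal phase: the resultant
length of {trial phase, hit-averaged reference phase}, `|cos(Δ/2)|` ∈ [0, 1].
Three regressions — logistic Y on X (total effect c), linear M on X (path a),
logistic Y on X and M (paths c′ and b) — are fitted by maximum
likelihood/least squares; every coefficient is divided by its standard error
(Wald SE from the observed information for the logistic fits), putting all
paths in t-statistic units, and the indirect effect is
`ab = t_a t_b / √(t_a² + t_b² + 1)`. Surrogates: the indirect effect is
z-scored against shuffles of the mediator's trial order; the total-minus-
direct contrast (t_c − t_c′) against joint shuffles of X and M relative to Y.
The reference phase is *not* recomputed under permutation — the shuffle moves
only what it is stated to move. Perfect separation in a logistic fit raises a
flagged numerical error; surrogate iterations that separate are dropped (the
run aborts if more than 10% do). A rank-based supplement
(`partial_spearman`) computes Spearman ρ(X, Y) and the first-order partial
ρ(X, Y | M); mediation shows as attenuation of the partial relative to the
marginal.

Mediation presumes the mediator follows the independent variable in time;
`check_mediator_direction` refuses the model when the PSI from the
independent-variable region to the mediator region is negative (override
downgrades the refusal to a warning; the pipeline overrides so that null
configurations, where ψ hovers around zero, still complete, and records the
guard value).

**Group inference.** Per-unit z maps are pooled with a one-sample t per cell;
cells exceeding the two-sided `cluster_alpha = 0.05` threshold form
4-connected clusters scored by mass (summed t); the null distribution of the
maximum cluster mass comes from sign-flipping whole unit maps — fully
enumerated (2^n flips, identity included, so p ≥ 2^-n) for n ≤ 12 units,
sampled otherwise. Scalar per-unit statistics use the same sign-flip logic as
a permutation t-test. Evidence at a peak cell is summarized by a one-sample
JZS Bayes factor: Cauchy(0, r) prior on the standardized effect, computed by
quadrature over the Zellner–Siow inverse-gamma mixture; default prior scale
r = √2/2 (the common toolbox default; r = √2 is equally available since the
choice is not canonical), with the heuristic labels anecdotal (< 3),
moderate (3–10), strong (> 10).

**Phase-reset diagnostic.** Total power (trial-averaged single-trial wavelet
power) and evoked power (wavelet power of the trial-averaged signal, i.e. of
the ERP — "trial-averaged amplitude" is read as the ERP, since an averaged
amplitude envelope could not detect a reset) are compared across pre/post
windows (±200 ms, 6–9 Hz). The 2×2 interaction is computed as a paired t on
the log-power contrast `(post−pre)_evoked − (post−pre)_total` with F = t²
(exact for two-level factors); log power stabilizes the variance. A positive
interaction — evoked power rising where total does not — is the signature of
stimulus-locked phase realignment.

## Spectral estimation

Morlet wavelets: Gaussian envelope σ_t = n_cycles/(2πf) times a complex
exponential, truncated at ±n_cycles/(2f), DC-corrected, unit-energy
normalized. Unit energy makes white-noise wavelet power flat across
frequency and band-integrated sinusoid power match signal variance to within
a few percent; every downstream statistic is phase-only or ratio-based, so
the normalization choice is otherwise inert. Coefficients are evaluated by
direct inner products at the requested center times (default grid 5–20 Hz in
1 Hz steps × −800..+800 ms in 50 ms steps, 6 cycles), so center times need
not sit on the sample grid; a requested cell whose support extends beyond
the epoch raises an error — never a silent zero-pad, which would corrupt
pre-stimulus phase. `wavelet_validity_mask` marks pre-stimulus cells whose
support crosses stimulus onset (t + n_cycles/(2f) > 0) for the edge-control
analysis. Filtering is zero-phase (forward–backward) Butterworth, since
one-pass filtering would bias phase.

## Synthetic generator

Two channels ("mPFC" leading, "MD" lagging), 4 s epochs at 250 Hz, 10 Hz
oscillations of unit amplitude in 1/f noise of matched standard deviation
(per-trace unit SD, exponent 1), 300 trials and 6 units at the reference
scale, ~71% hits. The directed lag (default 20 ms) is a pure circular time
delay of the shared cortical signal *including its broadband noise*: a
delayed sinusoid alone is indistinguishable from a phase-shifted one and
carries no phase slope, so the broadband pathway is what makes the PSI
ground truth well-defined.

*Condition mode*: outcomes drawn first (Bernoulli at the target hit rate);
cortical phase at the reference cell (−400 ms, configurable) is von Mises
around the optimal phase for hits and its antipode for misses with
concentration κ (κ = 0 → uniform, no structure); the thalamic channel mixes
the delayed cortical signal (weight = coupling gain) with an independent
oscillation-plus-noise.

*Mediation mode*: the mediator lives on the circle. Cortical phase is
uniform; thalamic phase = lagged cortical phase + von Mises coupling noise
whose concentration is chosen so the planted phase-difference consistency
(ISPC) equals the coupling gain; X and M are the proximities of the two
phases to their respective optima; outcomes are logistic in standardized
(X, M) with weights (c, b) and an intercept root-found to hit the target hit
rate. This makes hits and misses cluster at antipodal angles in *both*
channels and routes the cortical influence on behavior genuinely through the
thalamic phase. (A latent-Gaussian mediator squashed into [0, 1] is provided
separately by `make_behavior` for chain-level experiments; generated
directly, such a mediator leaves miss-trial thalamic phases dispersed rather
than antipodally clustered and cannot reproduce a positive thalamic
bifurcation.) The delayed broadband gain is outcome-gated — full coupling
for hits, zero by default for misses — planting the hit-specific directed
coupling the PSI contrast is designed to detect. Default strengths
(coupling 0.8, b = 1.5, c = 0.3) give a clearly detectable but not
deterministic effect at 300 trials.

*Staircase*: a k-up-m-down adaptive track (default 2 consecutive correct →
one step harder; 1 error → one step easier; level floors at 0, where the
blank interval is simply omitted) against a caller-supplied psychometric
function; the shipped logistic observer rises from chance 0.5 to ceiling 1.
The 2-down-1-up fixed point is P(correct) = √0.5 ≈ 70.7% correct; the
asymptote is estimated over the final half of trials (first half treated as
burn-in, a choice made here since no standard window exists).

All randomness flows from a single integer seed through one generator per
stage (pipeline stages draw child seeds deterministically from the run
seed), so identical configurations reproduce every statistic bit-identically.

### What the synthetic validation does not show

The generator emulates stationary sinusoids in 1/f noise with an exact
shared-delay pathway. It does not emulate non-stationary oscillatory bursts,
volume conduction, epileptiform artifacts, electrode referencing, or source
reconstruction; passing tests certify the estimators and their inference
under the planted model, not robustness to those phenomena. Two further
caveats:

* **Peak-selection inflation.** Selecting each unit's PBI-peak cell before
  fitting the mediation model inflates the absolute X→Y and M→Y links (under
  a global null the selected cells still carry selection-induced
  correlation). The mediation analysis is therefore a *relative* comparison
  of pathways, and the end-to-end null check tolerates the occasional
  mediation flag while all other checks stay null-calibrated.
* **Fast surrogate mode** is an approximation that rotates narrowband
  coefficients instead of re-transforming shifted signals; it matches
  faithful mode closely on the tested fixtures (planted-effect z within a
  null SD), but the faithful mode remains the reference implementation.

## Numerical choices

* Surrogate SD floor 1e−12: degenerate cells are masked NaN, never inflated.
* Cluster-forming threshold: two-sided t at α = 0.05 per cell (df = n−1);
  cluster statistic = mass; 4-neighbour adjacency; one-sided (positive) tail
  by default for directional hypotheses, two-sided available.
* Permutation p-values are one-sided with the identity included
  (p ≥ 1/n_perm); empirical percentiles use (1 + #{null ≥ obs})/(1 + n_perm).
* JZS quadrature uses adaptive integration on the mixture-of-g form and
  raises on non-convergence; it agrees with an independently coded
  Cauchy × noncentral-t marginalization to ~10 significant figures.
* Root-finding (staircase-equivalent intercept, von Mises concentration)
  uses bracketed Brent iterations with explicit unattainability errors.
* Epochs persist to a self-describing HDF5 layout (float64 data, time,
  uint8 outcomes, fs/labels/version attributes); configs to strict YAML
  (unknown keys are errors, round-trips are lossless and hashable).

## Scale of the shipped validation

The default demonstration (6 simulated units × 300 trials × 2 channels × 4 s
at 250 Hz; 1000 permutations for PBI/ISPC/mediation, 200 for PSI) runs in
about a minute on one CPU; the test suite's calibration batteries use
reduced grids (e.g. 40-trial, 3×3-cell null calibrations at 200 permutations
× 200 repetitions) chosen so each property check completes in minutes while
keeping Monte-Carlo error well inside the asserted tolerances.
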