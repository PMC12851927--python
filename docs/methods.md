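# Methods

This note documents the models, the statistical procedures, the synthetic
data they are validated on, and the choices made where the design was
genuinely open. Units are seconds and spikes/s throughout unless stated.

## The accumulator timer

Internal time is a scalar `T(t) = ∫₀ᵗ r` with a lick at the first `t` where
`T ≥ θ = 1`. The inflow `r` is constant within a trial; across trials
`r = θ/t*` with `t* ~ IG(μ = 1.3, λ = 12)`, so the unmanipulated
first-passage time reproduces the target inverse-Gaussian lick-time
distribution exactly (mean 1.3 s, SD `√(μ³/λ) ≈ 0.43` s).

Manipulations last 0.6 s with the final 0.3 s ramping linearly to zero
strength; the manipulated rate is a strength-weighted mixture of the normal
and manipulated values:

- **pause/slowdown**: `r_eff = r·(1 − s(t)·(1 − c))`, speed coefficient
  `c ∈ [0, 1]` (0 = full pause; 0.5 in the default experiment). A full
  pause loses exactly 0.45 s of accumulation (0.3 s full strength + the
  triangular half of the 0.3-s ramp); c = 0.5 loses 0.225 s.
- **rewind**: `r_eff = (1 − s)·r + s·r_decay` with `r_decay < 0`; the
  accumulator is clamped at zero, and a continuous dwell at zero longer
  than 0.32 s freezes the trial as a no-lick outcome.

Numerics: forward Euler at `dt = 1 ms` (a guard rejects `dt > 10 ms`) with
linear interpolation of the threshold crossing inside the final step, so the
unmanipulated lick time equals the drawn `t*` to floating precision; halving
`dt` moves any lick time by less than `dt`.

**Rewind decay default.** The magnitude of the rewind rate is not pinned by
the phenomenology alone, but its *form* matters: a decay proportional to the
trial's own rate (`r_decay = k·r`) makes the time-to-zero `0.6r/(k·r)`
identical across trials, so the 320-ms no-lick rule fires for either all
trials or none. An absolute decay (default `r_decay = −2.0 θ/s`, roughly
−2× the mean trial rate) gives slow trials longer zero-dwells than fast
ones and hence the observed mixture of delayed licks and no-lick outcomes.
Proportional decay remains available (`decay_per_trial=True`).

### Hazard rates and shifts

The hazard `h(t) = f(t)/(1 − F(t))` is computed in 20-ms bins as events
divided by the at-risk count at the bin start (no-lick trials enter as
right-censored at the 5-s no-lick horizon) and smoothed with a centered
5-bin boxcar. The unsmoothed hazard reconstructs the survival function
exactly (`∏(1 − h) = 1 − F`).

Two shift estimators between a reference and a comparison curve:

- **sigmoid** — both curves are fitted with a 4-parameter logistic
  (baseline, amplitude, midpoint, slope) restricted to times before the CDF
  reaches 80% of its final value (beyond which the at-risk denominator is
  small), and the 50%-rise midpoints are differenced. A half-maximum
  crossing is the fallback if the fit fails.
- **crossing** — the horizontal displacement at matched hazard levels,
  averaged over the levels the reference curve attains at its 50–75%-mass
  points. For a transient manipulation the post-offset hazard is an exact
  time-translation of the control hazard, and these levels are crossed
  post-offset, so this estimator reads the translation off directly. The
  50% point of a late-onset manipulated curve falls *inside* the
  manipulation window, where the hazard reflects the ongoing manipulation
  rather than the shifted timer state — no midpoint estimator can be
  onset-independent there — so the crossing method is used for the
  onset-independence analysis. At 10,000 trials it recovers a true 0.225-s
  pause shift to within one 20-ms bin at every onset tested (0.3–0.9 s).

Shift comparisons condition on the first lick occurring after the
manipulation onset in both conditions: trials resolved before the
manipulation carry no information about it, and because the hazard is
already a conditional quantity this restriction leaves it unchanged for
`t > onset`.

## The network model zoo

Populations follow `τ dhᵢ/dt = −hᵢ + Σⱼ Wᵢⱼ rⱼ + Iᵢᵇᵃˢᵉ + Iᵢᵉˣᵗ(t) +
Iᵢˢᵗⁱᵐ(t)` with `rᵢ = max(hᵢ, 0)` and τ = 10 ms, integrated by forward
Euler at `dt = 0.1 ms` (halving `dt` changes trajectories by < 0.1%).
"STR" stands for the whole subcortical loop (striatum → substantia nigra
reticulata → thalamus), which is why effective striatal self-excitation is
permitted.

The published architecture constraints fix each variant's *structure*
(where the unit eigenvalue lives, which area feeds which) but not numeric
weight values; the builder therefore synthesizes small weight matrices
satisfying the constraints and records them in output manifests. Two units
per area; temporal integration via a continuous attractor (an exact unit
eigenvalue of `W`), a leaky loop (leading eigenvalue 0.9), or feedforward
amplification (chains of 2-cell modules with internal eigenvalue 0.9,
feedforward links, and a global negative baseline so the step-input
strength sets the propagation speed). Eigenstructure is verified at build
time to 1e-9.

Baseline calibration solves `I_base = h* − W·max(h*, 0)` for a fixed point
with the target neuron at 5 spikes/s and verifies that the active
subsystem's leading eigenvalue is strictly below 1. Asymptotic stability
coexists with an integrating loop by keeping one partner of each loop just
below threshold at rest (h* = −0.02): the marginal direction only engages
once the cue-gated step input arrives. A consequence is that a suprathreshold
kick can transiently engage the loop; the excess then drains at the small
calibrated baseline drift, so full return to the fixed point takes a few
tens of τ rather than 10τ.

The cue-gated step input is calibrated per variant by bisection so the
unperturbed model lick — ramp-mode activity reaching 1, where ramp modes
are defined from the model's own activity by the same window-difference
rule as for recorded populations and normalized so 0 ↔ the target neuron's
5-Hz baseline and 1 ↔ 10 Hz — occurs 1.3 s after the cue.

Perturbations: transient ALM silencing (−10 to all ALM units, onset 0.6 s,
0.6 s including a 0.3-s ramp-down), D1-SPN inhibition (small negative
current to the striatal target unit; per-variant amplitudes −0.3, −0.1,
−0.1, −0.2, −0.02, −0.03 for the six positive-feedback variants), and
prolonged whole-trial versions of both.

**Signature classifiers** operate on normalized ramp-mode trajectories:

- *pause-and-resume* (ALM silencing, ALM ramp): the perturbed ramp
  recovers to ≥ half its pre-onset level shortly after the offset, resumes
  with a slope within 30% of control, and lags control by a time shift of
  the order of the stimulation duration (0.3–0.9 s window).
- *gradual decay / no jump* (D1 inhibition, striatal ramp): read from the
  deficit trace `control − perturbed` (the same quantity the decoded-time
  comparisons use, since a −0.03 current need not overcome the ongoing
  ramp drive in absolute terms): a meaningful deficit accrues by the
  offset (> 0.05 normalized units), at most half of it within the first
  100 ms (a clamped follower acquires its whole deficit within ~τ), and at
  least half persists 150 ms after the offset (no snap-back).

Among the six positive-feedback variants only the specialized striatal
integrator passes both; followers fail the gradual-decay test (fast dip,
jump recovery), and every variant whose ALM ramp collapses without an
external keeper (or tracks an external ramp) fails pause-and-resume. The
redundant variant keeps two *exact* unit eigenvalues via block-triangular
weak striatum→cortex coupling; its two integrators are input-independent,
so after ALM silencing the cortical copy resumes from the collapsed state
rather than re-converging — the behavior consistent with independence.

## Behavioral statistics

**Trial-history regression.** Lick time is regressed on previous lick times
(`T`), previous reward outcomes (`R`) and their interactions (`T×R`) at lags
1..k. The model grid is the 7 non-empty families of `{T, R, T×R}` crossed
with maximum lags 1–6 (42 models), scored by five-fold cross-validated MAD
explained `1 − R1/R2` (`R1` = median |held-out residual| of the model,
`R2` = of the intercept-only null, whose own score is 0 by definition); the
winner is refit on all data by OLS. Lagged regressors skip back to the most
recent licked trial across no-lick/no-cue gaps (keeping the design matrix
complete); dropping incomplete rows is available as `missing="drop"`.

**Hierarchical bootstrap.** Animals are resampled with replacement, then
sessions within each drawn animal, then trials within each drawn session;
the statistic is recomputed per iteration (1000 by default). CIs come from
the 2.5/97.5 percentiles; the one-sided p-value is the fraction of
iterations violating the alternative's direction. Under a nested-iid null
generator the empirical type-I error is at or below the nominal 5% level.

## Single-cell analyses

**Warping.** Post-cue spike times are rescaled by `t·(1 s)/LT`. The
across-trial variance comparison uses five 200-ms windows: time-locked
(0–1 s after the cue) versus phase-locked (centered at fixed fractions of
the trial but of fixed 200-ms *original* duration, so Poisson sampling
noise matches across the comparison), with the Poisson sampling term
(mean rate / duration) subtracted so only profile alignment differs.
Significance: a 1000-draw trial bootstrap of the corrected variance
difference whose 95% CI must exclude zero. Trials must cover the windows
(lick ≥ 1 s). This comparison has modest per-unit power at ordinary rates;
the validation suite uses ~1000 trials (and strongly modulated monotone
ramps for the planted-unit check), matching the scale at which the property
is stated.

**Ramp characterization.** Units with ≥ 50 trials licking in 1.25–1.5 s:
ten random half-splits; polynomial orders 1–8 fitted to the train PSTH
(1-ms bins, 200-ms causal boxcar, evaluated on a 10-ms grid from the cue to
the group's minimum lick time) and scored by test-PSTH MSE; the final order
is the mode over repeats with ties broken toward the smallest order
(parsimony). Monotonicity = the fitted derivative keeps one sign from cue
to lick; peak time = argmax of the fit.

**Modulation tests.** Pre-lick (0.2–0.5 s before lick) vs baseline (0–1 s
before cue), paired two-sided signed-rank. Photostimulation: rates within
50–250 ms of the stimulation onset, control vs stimulated trials, two-sided
rank-sum; units need > 1 spikes/s in control and ≥ 10 trials per condition,
and trials licking before the onset are excluded.

**Partial rank correlation.** `ρ_RP·U = (ρ_RP − ρ_RU·ρ_PU) /
√((1−ρ²_RU)(1−ρ²_PU))` on Spearman correlations; verified to 1e-10 against
a brute-force oracle (rank, regress out the conditioner's ranks, correlate
residuals). Nulls: trial-order shuffles of the history variable and, when
available, session permutations (1000 iterations each).

## Population modes and state-space analyses

Modes are unit-norm window differences of trial-mean activity versus the
pre-cue baseline (0–1 s): cue 0–0.3 s after cue, middle 0.5–0.8 s before
lick, ramp 0.2–0.5 s before lick, execution 0–0.3 s after lick.
Gram–Schmidt order: middle ⊥ ramp, cue ⊥ {middle, ramp}, execution ⊥ ramp
(dot products < 1e-10); the trial-history mode (per-neuron Spearman
correlation of ITI firing with the regression-predicted lick time,
normalized) is not orthogonalized.

Variance explained divides the squared projection by the squared total
rate, both baseline-subtracted (0–0.2 s before the cue; the trial-history
mode skips the subtraction); orthonormal modes obey Bessel's bound.
Mode angles use cosine similarity against an entry-shuffle null (cosine
shrinks toward 0 with dimensionality, so raw values are not comparable
across population sizes).

Population correlation matrices correlate unit-vectors of 200-ms-binned
mean activity between a reference trial group and comparison groups;
the peak trace takes, per reference bin, the comparison time of maximal
correlation when it exceeds 0.8 (zero-variance columns stay missing, never
0). The 2-D vector field pools 50-ms displacement vectors in the
(middle, ramp) plane — control-SD-normalized without mean subtraction, so
0 means zero spiking — into 0.5-wide spatial bins with > 30 points;
stimulation vectors come from 100–400 ms after the inhibition onset; bins
whose control vector lies within π/6 of the through-origin line at that
location are excluded (flow along the origin line cannot distinguish
rewinding from collapse toward zero). The exclusion reads the "origin
direction" as the two-argument arctangent of the bin position.

Pseudo-sessions pool units across sessions: more than 10 trials in each of
the six lick-time ranges (0.80–1.10, 1.10–1.25, 1.25–1.40, 1.40–1.55,
1.55–1.70, 1.70–2.00 s), 50 randomly drawn unperturbed definition trials
(lick 1–3 s), with definition and projection trials strictly disjoint.

## kNN time decoding

Each 50-ms population vector from 1 s before the cue to the lick is a
training point labelled with the remaining time to lick; a test vector is
decoded as the mean label of its k = 30 nearest neighbors (k = 20–50 give
the same conclusions). Binned rates get a 200-ms *causal* boxcar (no future
leakage). Distances are Mahalanobis in the space of the top PCs explaining
90% of the training variance. The covariance model is the **Poisson
observation covariance**, implemented as a square-root variance-stabilizing
transform followed by Euclidean distance on the retained components.
Whitening by the total PC eigenvalues is the configurable alternative
(`metric="pc_whiten"`), not the default: with near-isotropic single-bin
Poisson noise, ~24 of 30 PCs are needed to reach 90% variance and total-
covariance whitening equalizes signal components with noise components,
capping recovery well below what a maximum-likelihood read-out of the same
data achieves.

Session QC: > 300 trials and ≥ 5 units; decodability = Pearson r between
decoded lick time at 0.6 s (bin time + decoded remaining time) and actual
lick time on held-out unperturbed trials, with 0.35 as the downstream
inclusion threshold. The test set is 100 random unperturbed trials plus
all perturbed trials (simple random selection).

**Matched pairs.** Each perturbed trial is paired with the unperturbed
test trial whose decoded time at the perturbation onset (0.6 s) is
closest. Deficits (perturbed − control decoded remaining time) are read
per pair over jointly defined bins — controls licking early would
otherwise bias the surviving-trial average — just after the stimulation
plus the smoothing width (suppressed-rate bins during silencing decode
arbitrarily). kNN label averaging shrinks decoded values toward the label
mean, so the decoded clock runs slow; the mean per-trial slope of the
matched controls' decoded trajectories calibrates decoded seconds back to
real seconds. Recovery time is when the perturbed decoded time returns to
its pre-stimulation level, searched from the peak deviation onward.
An oracle test (feeding the matcher noiseless clock-derived decoded values)
confirms the matching machinery recovers planted pause and rewind shifts
exactly; with spiking data the residual kNN regression-dilution vanishes
by ~80 units per session.

## Synthetic sessions and what they do (not) show

The generator plants: a lick-time process `μₙ = β₀ + Σ β_T,k·LT₍ₙ₋ₖ₎ +
Σ β_TR,k·LT₍ₙ₋ₖ₎·R₍ₙ₋ₖ₎` with inverse-Gaussian dispersion (λ_gen = 12,
floor 0.2 s), block-switched delays (30–70 trials), ITIs 1 s + Exp(3 s)
capped at 7 s, ~10% cue-omitted trials; and Poisson units (1-ms
resolution) combining a 5-Hz baseline, cue-to-lick profiles — 40% monotone
smoothstep ramps peaking at the lick and 60% bumps tiling peak phases
0.15–1.0 (populations unfold as sequences) — that are temporally scalable
in 70% of units and absolute-time otherwise (peak amplitude ~15 spikes/s
above baseline), tonic trial-history coding (h_i·z, 40% of units, 2
spikes/s per SD of predicted lick time), cue-gated speed-input units
coding 1/(intended lick time) (25%, 4 spikes/s per SD; the
integrator-input signal — *intended* rather than realized, because a
perturbed trial licks late for reasons downstream of its drive), and a
mild shared per-trial gain (SD 0.10). Perturbed trials run an internal
clock that pauses (with multiplicative rate suppression to 2%) or rewinds
(2 clock-units/s); ramps read the clock, so spikes and lick times shift
consistently and the planted shift is recorded per trial.

Fixture sizes used by the validation suite are the scales at which the
corresponding properties are stated or at which the estimators are
well-conditioned: 600 trials for regression recovery; 50 units × 200 trials
for trial-history-mode loadings; ~1000 trials for the warping-variance
property; 30 units × ~400 usable trials with strong modulation
(25 spikes/s ramps) for the decodability benchmark; 80 units × 500 trials
(a pooled dual-probe session) for matched-pair shift recovery.

What passing these tests shows: the estimators are consistent and correctly
implemented under the generative assumptions they target. What it does not
show: robustness to features of real recordings the generator omits —
non-Poisson spiking (bursting, refractoriness), drift and unit instability,
correlated noise beyond a shared gain, cross-area lag structure beyond the
common lick-time coupling, or behavioral states (disengagement, satiety)
beyond the engagement-filter contract.

## Degenerate inputs and tie-breaks

Empty trial sets, all-censored hazard inputs, constant vectors in
correlations, zero mode vectors, zero-variance correlation columns, and
sessions failing QC all raise explicit errors or are emitted as missing
values (never silently 0). Nearest-neighbor ties resolve by training-point
index; polynomial-order ties resolve to the smallest order; the long-ISI
threshold for fast-spiking-interneuron classification defaults to a 10%
fraction with the "long" cutoff configurable (2 s), as the criterion is not
otherwise pinned down.
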