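# Methods

## Model family

### Oscillated temporal expectation model (OTEM)

Two preparedness threads, one per prospective target (congruent or
incongruent with the prime), accumulate from prime onset:

    de_alt/dt = φ_alt(t) · ρ_m(t) − μ · e_alt,     0 ≤ e_alt ≤ ζ,  e_alt(0) = 0.

At target onset τ the target's thread races alone to the response threshold
b at rate ν, so the expected RT is (b − e_target(τ))/ν, and the observed RT
carries multiplicative log-normal noise: log RT_obs ~ N(log RT_exp,
σ_noise²).  The multiplicative reading of the log-normal noise was chosen
because it yields a proper closed-form likelihood; an additive reading would
not, and the two are never mixed.

**Attentional gain.**  φ_C = 1 + D, φ_IC = 1 − D with

    D_p(t) = e^{−κt} sin(2πf t + θ_prime)
    D_m(t) = e^{−κ(t−τ_mask)} sin(2πf (t−τ_mask) + θ_mask)   for t ≥ τ_mask

and D = clip(D_p + D_m, −1, 1) under additive reset or D = D_p before /
D_m after mask onset under substitutive reset.  The clip keeps both gains
nonnegative; the initial amplitude is fixed at 1 (an amplitude parameter
would trade off exactly against ν and b).  For unmasked tasks τ_mask → ∞.
The prime component keeps decaying on its own clock after mask onset in
additive mode.  f is fixed at 3.3 Hz in standard fits and freed only in the
frequency sweep.

**Temporal expectation.**  The belief over target-onset times lives on the
session's 20 ms SOA grid (the union over blocks — no block-aware mechanism
exists, which is precisely what produces border jumps and sequential
effects).  It starts uniform and after every non-excluded trial moves toward
the perceived onset of that trial,

    p_m = (1 − α) p_{m−1} + α p'_{m−1},

where p' is a Gaussian centred on the true onset with scalar-timing sd
k·τ (k = 0.13), evaluated at the grid points and renormalized (density
sampling rather than bin integration; the difference is negligible at 20 ms
spacing against sd ≥ 0.13τ).  τ is measured from the task's SOA reference:
prime onset for unmasked, mask onset for masked tasks.  Within a trial,
conditioning on "no target by t" renormalizes the remaining mass; the leading
value is the hazard rate, and the temporal gain is the discounted expectation

    ρ_m(t) = Σ_{t′≥t} q_m(t′|t) · γ^{(t′−t)/20 ms}.

γ is a per-20-ms-step discount (the equations give no time unit for it).
When the remaining mass is numerically exhausted (< 1e−250) the target is
treated as certainly imminent (hazard and gain 1).  Before the reference
onset all mass is in the future, so the gain simply carries extra discount
steps.

**Accumulation bookkeeping.**  Euler integration on a 20 ms grid aligned to
the SOA grid (belief resolution is 20 ms and the RT structure of interest
has ≥ 300 ms periods); dt is configurable and a refinement test confirms
O(dt) behaviour.  The accumulation clock starts at prime onset in both task
kinds; the belief machinery is anchored at the SOA reference.  Expected RT
is floored at 1 ms to guard the likelihood's logarithm, and ζ < b is
enforced structurally during fitting (ζ is optimized as a fraction of b).

### Rival models

The **oscillated urgency model** replaces accumulation with an instantaneous
readout e_alt(t) = clip(φ_alt(t)·h_m(t), 0, ζ) and applies a single reset
phase θ to both prime and mask (additive machinery); 7 free parameters
(α, κ, θ, ζ, ν, b, σ_noise).  The **constant accumulation model** drops
expectation and oscillation: the prime drives its direction's accumulator at
+λ_s, the mask reverses it to −λ_s, the target drives its own accumulator at
+λ_s (the other only leaks), all with growth-decay rate μ and a pre-target
ceiling ζ; the response fires when the accumulator difference reaches the
threshold (fixed at 1, making a separate b redundant), computed in closed
form after target onset; 4 free parameters.  The **extended decision stage**
(noise-free leaky competing accumulators with mutual inhibition η and
per-trial Gaussian rate draws) is simulation-only and is never fitted.

## Fitting

Per participant, maximum likelihood on correct, non-excluded trials, with
beliefs replayed in session order over all non-excluded trials.  The search
runs L-BFGS-B in unit-box coordinates (so numerical gradient steps are
comparable across parameters spanning 0.01–50): a Latin-hypercube pool of
candidate starts (eight per requested restart, at least 40) plus structured
starts on a uniform phase grid is screened by raw likelihood; the best
`n_restarts` get short bounded runs, and the top three survivors a long
polish.  Everything is seeded and reproducible.  Bounds: α, γ ∈ [0,1];
μ, κ ∈ [0,20] s⁻¹; phases in [−π, π) (wrapped on report); ζ/b ∈ [0.02,0.98];
ν ∈ [0.5,100] s⁻¹; b ∈ [0.1,50]; σ_noise ∈ [0.01,2]; λ_s ∈ [0.05,100].

Multi-condition fits (the two prime-to-mask-interval conditions) share one
parameter vector except a per-condition b and σ_noise; ζ is tied to the
smaller threshold so it remains shared.  Goodness of fit is summarized by
AICc = 2·NLL + 2k + 2k(k+1)/(n−k−1); group-level comparison uses
random-effects Bayesian model selection with evidence approximated by
−AICc/2: variational Dirichlet updates, exceedance probabilities by
Monte-Carlo sampling of the posterior (10⁵ seeded draws), and the protected
exceedance probability PXP = EP·(1−BOR) + BOR/K, where BOR compares the
random-effects free energy against the equal-frequency null.

The frequency sweep refits the model with f fixed at each grid value
(0–16 Hz).  At 0 Hz the oscillation degenerates to a decaying envelope whose
phases are no longer continuous parameters; only the envelope sign remains
and is treated as a discrete model choice (best of the sign combinations),
so the 0 Hz model has two fewer free parameters.

The likelihood engine is vectorized across trials (delta-rule replay as an
exponential moving average, suffix-sum recurrences for hazard and discounted
gain, a single Euler pass capturing preparedness at each trial's onset) and
the three inner kernels are numba-compiled; unit tests pin the engine to the
per-trial reference operations to ~1e−6 ms.

## Analysis pipeline

Exclusions: time-outs (no response or RT over the design limit), premature
responses (< 100 ms — the exclusion is standard but no cut-off is canonical,
so 100 ms is a package default), then per-participant ±3 SD on the surviving
RTs pooled across SOA and congruency.  SOAs above 800 ms are dropped before
analysis of the 0–980 ms designs.  Slow trends are per-participant,
per-congruency least-squares fits of a + c·e^{−SOA/τ_d} (τ_d bounded to
[20 ms, 10 s]; linear fallback, flagged, on non-convergence); detrended
series are the residuals, with missing SOA cells linearly interpolated
before spectral analysis.  Amplitude spectra use the DFT at 20 ms sampling,
normalized 2|X_k|/N over the positive-frequency bins.  Permutation
thresholds shuffle each participant's detrended series across SOAs, average
spectra across participants, take the 95th percentile per frequency
(uncorrected) and the maximum of those across frequencies (corrected);
the calibration test measures the per-frequency-point false-positive rate of
the corrected threshold, which is what this max-of-quantiles construction
controls.  The 3–5 Hz phase difference is the circular mean of the per-bin
congruent-minus-incongruent phase angles over bins centred in [3, 5] Hz.
Rayleigh tests use n·R̄² with the standard series approximation for p;
the Watson–Williams circular ANOVA uses the 1 + 3/(8κ̂) correction with the
usual three-regime κ̂ estimate.  Priming windows are SOA 0–60 ms (positive)
and 100–160 ms (negative).  Jump tests compare, across participants, mean RT
at the first SOA of a block against the last SOA of the preceding block
(one-tailed paired t per border and congruency); the base-rate variant runs
the same 11 unique SOA pairs (22 comparisons with congruency) on the
unblocked 40-SOA design.  Fisher's exact test uses the probability-mass rule
for the two-sided p.  Sequential effects regress the current RT on the
previous three SOAs with the previous three RTs and the current SOA as
nuisance covariates (OLS per participant, group t-tests on the lagged-SOA
coefficients; the first three trials of a session are dropped).

## Synthetic cohorts

Cohorts stand in for human groups: each participant gets a parameter vector
(fixed demo values by default, or uniform draws within given ranges) and a
fully simulated session; every trial order, noise draw and parameter draw
descends from one seed.  The demo operating point is

    α = 0.15, γ = 0.95 /step, μ = 1.0 s⁻¹, κ = 1.5 s⁻¹,
    θ_prime = 0, θ_mask = π, ζ = 1.0, ν = 3.0 s⁻¹, b = 1.6, σ_noise = 0.05,

chosen once to land in the empirically reported regime: mean RTs ≈
380–530 ms, positive window effects ≈ +10–17 ms and negative ≈ −3–5 ms in
masked tasks, sustained positive slow-trend priming at every SOA in unmasked
tasks, near-cancellation (|effects| < 5 ms) for additive resets at zero
prime-mask interval, and ~20 ms residual RT noise (the practiced-subject end
of plausible variability, which also keeps the model's parameters
identifiable at single-session scale).  What the generator does *not*
emulate: error responses (the base models apply to correct RTs only; errors
exist only in the simulation-only extended decision stage), fatigue or
practice drifts, fast sequential dependencies beyond belief updating, and
any block-aware strategy.  Passing tests therefore show that the pipeline
recovers the model's own structure under in-model conditions, not that the
model is true of human data.

## Known limitations

- **Reset-phase label degeneracy.**  In masked-only designs the two
  oscillation components differ only by onset time and an amplitude factor
  e^{κτ_mask}; swapping their phases (with small compensations in μ, κ, ζ,
  ν, b) reproduces the noise-free expected RTs to < 0.3 ms RMS.  Masked data
  identify the *combined* post-mask wave, not the component labels, so
  per-participant phase estimates land in either mode at roughly even odds
  at realistic noise; only the learning and discount parameters (and σ) are
  sharply identifiable from a single masked session.  Designs that vary the
  prime-mask interval within participant (the two-interval conditions with
  shared phases) break the swap and are the appropriate setting for phase
  inference — exactly the role they play in the experimental literature this
  model family addresses.
- The urgency and constant-accumulation models are implemented for fitting
  and comparison but their demo parameter sets are illustrative, not tuned
  to reproduce any phenomenon.
- Belief support is the session's SOA grid; onset times off the 20 ms grid
  are not representable.
- The permutation correction controls the per-frequency-point error rate of
  the corrected threshold (see above), not the family-wise rate over an
  arbitrary number of exchangeable frequencies.
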