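# Methods

This note documents the statistical model behind `adaptlrt`, the
conventions and numerical choices the implementation commits to, what the
simulator does and does not emulate, and known limitations.

## Data model and estimators

Subjects are iid tuples (R, Z, T, C*): calendar entry time, arm indicator
(1 = experimental), event time since entry, random dropout time since
entry (∞ when absent).  An analysis at calendar time t observes, for each
subject with R ≤ t, the pair X(t) = T ∧ C* ∧ (t−R)⁺ and
δ(t) = 1{T ≤ C* ∧ (t−R)⁺}; administrative censoring is therefore induced
by the analysis date and is consistent under re-truncation (a snapshot at
a later date, re-censored to an earlier horizon, reproduces the earlier
snapshot exactly — a tested invariant).  Subjects with R = t are enrolled
with zero follow-up and contribute to nothing.

Kaplan-Meier and Nelson-Aalen estimators use the counting-process tie
convention: events precede censorings at equal observed times, and the
risk set at s counts subjects with X ≥ s.  All times are unitless reals;
the bundled scenario defaults read naturally in years.

## Weighted log-rank statistics

For a weight Q̂ evaluated from the pooled Kaplan-Meier estimate, the
statistic and covariance at analysis time t are

    T_ℓ = n^{-1/2} Σ_{events i} Q̂_ℓ(X_i) (Y₁(X_i)/Y(X_i) − Z_i)
    Σ̂_{ℓℓ'} = n^{-1} Σ_{events i} Q̂_ℓ Q̂_ℓ' (Y₁/Y)(1 − Y₁/Y)

with n the number of subjects enrolled by t.  **Orientation.** The sign
is chosen so that positive values indicate experimental-arm benefit
(expected minus observed events in that arm).  This is the only
orientation under which the one-sided cone restriction of the
combination statistic, the stage-2 p-value 1 − Φ(S₂), and the planning
drift (positive when the control hazard exceeds the experimental hazard)
are mutually consistent; the source literature's "observed − expected"
phrasing carries the opposite sign for the same construction.

Fleming-Harrington weights use left limits of the pooled curve — the
value strictly before any tie block — with the convention 0⁰ = 1.
Both weight parameters must be ≥ 0 (positive weights keep the one-sided
test valid).

Stage increments rescale the interim statistic to the final-analysis n
(so the difference telescopes) and divide by the variance increment.  A
variance increment ≤ 1e−12 raises an error ("no second-stage
information"); the study runner counts such replicates as failures rather
than dropping them.  Weights are recomputed from each analysis's own
pooled estimate (the literal reading; the asymptotic independence of
increments rests on the weight limit being calendar-time-free).

## One-sided combination test and wild bootstrap

The stage-1 statistic is W = max over nonempty weight subsets L of
T_Lᵀ Σ̂_L⁻ T_L, restricted to subsets with Σ̂_L⁻ T_L ≥ 0 componentwise,
and 0 if no subset qualifies.  Σ̂⁻ is the Moore-Penrose pseudoinverse
with singular values below m·σ_max·1e−12 treated as zero; the cone
condition uses a 1e−12 slack.  Duplicate weights are rejected when the
design is constructed (linear independence requirement).

No usable closed-form null distribution exists, so the p-value comes
from a wild bootstrap: one Rademacher multiplier per subject applied to
the subject's entire integrated weighted residual (the δ-weighted term
of the statistic sum).  Because the multipliers square to one, Σ̂ is
reused unchanged for the bootstrap statistics.  The p-value is the
add-one estimator (1 + #{W* ≥ W})/(B + 1), hence never 0; B defaults to
1000.  An exact-enumeration mode over all 2^(#events) sign assignments
exists for small fixtures and is the oracle in the tests.  The
construction's null behaviour is guarded by a conservativity property
test (empirical p-value CDF below the diagonal up to one-sided KS noise).

## Spline survival models

Each arm's interim survival curve is fitted separately (never a joint
model — a joint model would force a fixed difference pattern such as
proportional hazards on the hazard scale).  A natural cubic spline
η(x) in log time x models the link-transformed survival: hazard scale
g(u) = log(−log u), odds scale log(1/u − 1), normal scale −Φ⁻¹(u); with
zero internal knots these are exactly Weibull, log-logistic and
lognormal, and the tests pin each reduction to an independent parametric
MLE.  Boundary knots sit at the smallest and largest uncensored log
times, internal knots at the quantiles j/(p+1) of the uncensored log
times (linear-interpolation quantiles; the quantile type is a committed
convention, not given by theory).  The truncated-power natural-spline
basis is linear outside the boundary knots, which *is* the extrapolation
rule: the transformed survival continues with its boundary slope.

Fitting maximises the right-censored log-likelihood with L-BFGS-B from a
moment-based start (higher-knot models start zero-padded), with up to
three jittered restarts.  Validity of the implied hazard requires η
nondecreasing: a soft quadratic barrier on a 128-point grid steers the
optimizer and a hard 512-point check over [k_min − 2, k_max + 2] rejects
violating fits; rejected or failed fits are excluded from AIC selection
with a warning.  The default grid is {0, 1, 2} internal knots × 3 scales
= 9 models per arm; selection is mechanical minimum-AIC with
deterministic tie-breaks (fewer knots, then hazard < odds < normal).
Mechanical AIC is known to be imperfect — especially for late-separation
patterns, where few late events exist at the interim and the selected
0-knot models can miss the separation; the full model table is exposed
in the trial trace for inspection.  If every fit in an arm fails, the
procedure falls back to the neutral log-rank weight FH(0,0) with a
warning.

## Planning machinery (conditional error / power)

Under planning assumptions — accrual CDF F̃_R (default: the design's
known accrual law), dropout CDF F̃_C* (default: none), allocation
r = P[Z = 1], and per-arm survival/density/hazard functions (typically
the extrapolated splines) — the at-risk probability is

    π̃_k(t, s) = P[Z=k] · F̃_R((t−s)⁺) · (1 − F̃_C*(s)) · S̃_k(s)

and the drift and variance of a weighted statistic are

    ξ̃(t)  = ∫₀ᵗ Q̃ · π̃₀π̃₁/(π̃₀+π̃₁) · (λ̃₀ − λ̃₁) ds
    σ̃²(t) = ∫₀ᵗ Q̃² · π̃₀π̃₁/(π̃₀+π̃₁)² · F̃_R((t−s)⁺)(1−F̃_C*(s))
             · ((1−r) f̃₀ + r f̃₁) ds

The variance integrand's ratio has a squared *denominator* only: it is
the limit of (Y₁/Y)(1 − Y₁/Y) times the pooled event intensity, and
collapses to F(t)/4 in the balanced instant-accrual null case (a frozen
test value).  The Fleming-Harrington weight limit Q̃ is w(ρ,γ) composed
with the assumed *pooled* CDF, mixed by the allocation ratio — the
empirical weight's large-sample limit — not the control CDF.

**Scaling.** ξ̃ and σ̃² are full-cohort (per-tuple) limits while the
observed statistic is scaled by the enrolled count, so
Var(T(t)) ≈ σ̃²(t)/F̃_R(t); the enrolled-count factors cancel entirely
from the *standardized* increment, whose mean is √n_total·Δξ̃/√Δσ̃² with
n_total the number of randomized subjects.  The planning formulas as
printed in the source literature omit this √n factor (their display
would make conditional power degenerate in the limit); the inserted
factor is validated by a simulation test that matches the formula to the
empirical stage-2 rejection rate within Monte-Carlo error.

Conditional error uses closed forms for the shipped combiners
(inverse-normal: α̃₂ = 1 − Φ((Φ⁻¹(1−c) − w₁Φ⁻¹(1−p₁))/w₂); Fisher:
min(1, c/p₁)) and monotone root-finding for any other combination
function.  The selection rule picks the candidate maximising conditional
power, ties to the smallest index.

Integrals use piecewise 64-point Gauss-Legendre quadrature with segments
split at the accrual kink and quartered; on the smooth integrands this
matches adaptive quadrature to ~1e−9 or better while evaluating the
vectorized integrands in a few array calls.

## Design bounds and level

O'Brien-Fleming two-stage bounds use z-boundaries (z√2, z) under the
independent-increments bivariate normal model with equally spaced
information, solving the one-sided level condition by root finding on
the exact bivariate normal probability; at α = 0.025 this gives
α₁ = 0.002583 and c = 0.023996, and equal inverse-normal weights
w₁ = w₂ = 1/√2 are the matching default.  Equal information spacing is a
convention (the calendar interim need not sit at half the information);
alternative spacing is configuration.  Pocock-style common bounds are
provided analogously.  A futility bound α₀ < 1 is treated as
non-binding, i.e. conservative.  `verify_level` recomputes the attained
level by integrating the closed-form conditional error; design
construction is checked against it to 1e−4 at the orchestrator entry
points.  Boundary comparisons are ≤ throughout.

## Simulator

The stated world: uniform accrual on [0, 6] years, exponential control
arm with hazard −log(0.7) (30% annual event rate), no random dropout,
analyses at years 5 and 8, balanced arms.  Alternatives make one
Fleming-Harrington weight locally optimal by setting the log hazard
ratio proportional to that weight at the control CDF:
λ₁(s) = λ₀ exp(θ·w(ρ*,γ*)(F₀(s))), θ ≤ 0.  (ρ*,γ*) = (0,0) is exact
proportional hazards and is sampled in closed form; other deviations
tabulate the cumulative hazard on a 4096-point log-spaced grid to
t₂ + 10 and invert by monotone interpolation.  The external
constructions cited for such "FH-optimal" alternatives are not
reproduced verbatim anywhere accessible; the log-HR-proportional form is
the canonical locally optimal shape, so absolute calibrated θ₀ values
are implementation-specific — only powers evaluated *at this
implementation's own θ₀* are comparable across implementations.

Effect-size calibration solves for θ in the bivariate-normal two-stage
power (stage-1 mean √n·ξ̃(t₁)/σ̃(t₁), increment mean √n·Δξ̃/√Δσ̃²,
correlation w₁ between the stage-1 z and the combined z) by bracketed
root finding to 1e−6.  At the calibrated θ₀ the simulated power of the
matched design reproduces the target within Monte-Carlo error — the
end-to-end check of the whole drift pipeline.

Replicates are seeded per index from a spawned seed stream, so study
results are invariant to the worker count.  Replicate failures are
counted and reported, never silently dropped.

What the simulator does **not** emulate: random dropout by default
(supported in the data model and planning formulas, not exercised by the
stated scenarios), covariates beyond the binary arm, non-uniform or
data-dependent accrual, sample-size recalculation or schedule changes,
and more than two stages.  A green simulation test therefore establishes
correctness of the procedure under the stated world, not robustness to
those features.

## Known limitations

- The wild-bootstrap residual construction (one multiplier per subject on
  the δ-weighted residual) is one of several asymptotically equivalent
  choices; centring/studentization variants exist.  The null
  conservativity property test is the guard.
- Type-I error at small samples shows the usual slight anti-conservatism
  of normal-approximation log-rank inference; a permutation variant
  would address it but is out of scope.
- Conditional power inherits the well-known tendency to extreme values;
  predictive power is not implemented.
- Spline extrapolation beyond the interim horizon is a modelling
  assumption, and AIC-selected 0-knot models can miss late separation;
  expert review of the fitted model table is advisable in real use.
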