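# Methods

This note records the statistical model, the estimators, the numerical
conventions, and the design decisions behind `winpred`, in enough detail to
reconstruct every computed quantity.

## Data model

A subject contributes covariates `Z ∈ ℝᵖ`, an optional stratum label, and an
ordered event history: zero or more nonfatal events followed by exactly one
terminal record (death or censoring). Internally each subject is reduced to
`(X, δ_D, T, Z, 𝒮)`: last observation time `X = D ∧ C`, death indicator,
first nonfatal time `T` (absent if none observed), covariates, stratum.
Recurrent nonfatal events are accepted and retained, but the default win
rule uses only the first — later events become relevant only under
alternative win functions, which are out of scope. Subjects with zero
follow-up are rejected: they can never enter a comparison and would break
risk-set bookkeeping.

## The win rule

For a pair (i, j) at horizon `t`, comparisons run over the *shared* window
`u = t ∧ X_i ∧ X_j`:

1. if exactly one subject dies in the window, the survivor wins;
2. if neither dies in the window, the subject whose first nonfatal event is
   later (or absent) wins, provided the other's occurred within the window;
3. otherwise the pair is tied (no decisive event, or an exact tie in the
   deciding event time).

Two conventions matter and are deliberate:

* **Closed window.** An event at exactly `u` counts as observed. A
  decedent's follow-up ends at the death time, which therefore always sits
  on the boundary of any window it closes; with an open window no death
  could ever produce a win.
* **Exact ties → mutual tie.** The theory assumes continuous event times;
  with discrete or rounded data, two deaths (or two first nonfatal events)
  at the same instant yield (0, 0) rather than an arbitrary order.

Horizon `∞` means "no cap": the window is each pair's full shared follow-up.

## PW estimation

With win indicators `δ_ij(t)`, comparability `R_ij = δ_ij + δ_ji`, and the
model win probability `μ(Z_i, Z_j; β) = expit{βᵀ(Z_i − Z_j)}` (computed via
the logistic of the difference, which is overflow-safe), the coefficient
vector solves

    U(β) = Σ_{i<j} (Z_i − Z_j) {δ_ij(∞) − R_ij(∞) μ(Z_i, Z_j; β)} = 0.

`U` is the gradient of a concave pseudo log-likelihood, so Newton iteration
from `β = 0` with the exact Jacobian `−Σ R_ij μ(1−μ)(ΔZ)(ΔZ)ᵀ` is globally
stable; convergence is declared when the pair-normalized score max-norm
falls below 1e−10 (at most a handful of iterations; the tight tolerance
makes the two-sample closed form below hold to ≤1e−8 in β̂ itself). The
O(n²) pairwise table is materialized once and reused by the score, the
Jacobian, the variance pieces and all diagnostics.

With a single binary covariate the equation reduces algebraically to
`β̂ = log(W₁/W₀)`, the log ratio of inter-group win counts — the classical
two-sample win ratio — which the tests verify by brute-force enumeration.

Sampling variance uses the U-statistic sandwich. With per-subject
projections `κ̂_i = (n−1)⁻¹ Σ_{j≠i} (Z_i−Z_j) M_ij(∞; β̂)` and slope
`Â = −(n choose 2)⁻¹ Σ R_ij μ̂(1−μ̂)(ΔZ)⊗²`,

    Var(β̂) = (4/n) Â⁻¹ {n⁻¹ Σ_i κ̂_i κ̂_iᵀ} Â⁻¹,

implemented in the algebraically identical unnormalized form
`J⁻¹ (Σ_i g_i g_iᵀ) J⁻¹`, `g_i = Σ_{j≠i}(Z_i−Z_j)M_ij`, which carries over
unchanged to stratified fits where strata differ in size.

## Cox model for the time to first event

The tie-breaking first event is `T̃ = D ∧ T`, observed as
`X̃ = min(first nonfatal, X)` with indicator `δ̃`. The package fits a
standard Cox proportional-hazards model to `(X̃, δ̃, Z)` with its own
Newton/step-halving solver (Breslow tie handling throughout, risk sets
`I(X̃ ≥ u)`, score tolerance 1e−9 per subject, γ = 0 start), because the
downstream uncertainty work needs the internal aggregates that packaged
fitters do not expose: per-distinct-event-time `ŝ⁽⁰⁾, ŝ⁽¹⁾, ŝ⁽²⁾`, the
ratio `ℰ̂ = ŝ⁽¹⁾/ŝ⁽⁰⁾`, the per-subject-normalized information `ℐ̂`, the
Breslow baseline jumps, and per-subject martingale integrals. The fitter is
cross-checked in the tests against lifelines (coefficients, baseline,
variance) and against direct numerical maximization of the explicit partial
likelihood; with no covariates the baseline reduces exactly to the
Nelson–Aalen estimator. Monotone likelihoods (perfect separation) are
detected by verifying that doubling γ̂ strictly decreases the partial
likelihood — a score-only criterion would "converge" at a large finite γ̂ —
and reported as non-convergence. Efron tie handling is intentionally not
offered: the influence algebra below assumes the Breslow baseline, and
mixing conventions would break its internal consistency.

Stratified fits share γ across strata with stratum-specific baselines. All
`ŝ⁽ᵏ⁾` are normalized by the *total* n in every stratum, which keeps each
subject's influence contribution on a common 1/n scale.

## Prediction and uncertainty

Point prediction composes the two fits:

    ν̂(t) = Ŝ(t|z) Ŝ(t|z*),   ŵ(t|z,z*) = (1 − ν̂(t)) μ̂(z,z*),

with `Ŝ(t|z) = exp{−e^{γ̂ᵀz} Λ̂₀(t)}` evaluated as a right-continuous step
function. Beyond the last observed time the baseline is carried forward and
a warning flags the extrapolation. The trinomial identity and the constancy
of `ŵ/l̂ = exp{β̂ᵀ(z−z*)}` hold by construction, at machine precision.

The pointwise variance is the empirical second moment of estimated
per-subject influence contributions

    IF_i(t) = μ̂ Ŝ(t|z) Ŝ(t|z*) [ (Ĥ(t;z)+Ĥ(t;z*))ᵀ ℐ̂⁻¹ ∫(Z_i−ℰ̂)dM̃_i
              + (e^{γ̂ᵀz}+e^{γ̂ᵀz*}) ∫₀ᵗ ŝ⁽⁰⁾(u)⁻¹dM̃_i(u) ]
              − 2 ŵ (1−μ̂) (z−z*)ᵀ Â⁻¹ κ̂_i,

    σ̂²(t) = n⁻² Σ_i IF_i(t)²,

with `Ĥ(t;z) = e^{γ̂ᵀz} ∫₀ᵗ{z−ℰ̂(u)}dΛ̂₀(u)`; all integrals are finite sums
over distinct event times. The win–loss covariance `σ̂₁₂` is the analogous
cross moment of the win and loss contributions (the loss curve is the win
curve with z and z* exchanged). No finite-sample degrees-of-freedom
correction is applied. This plug-in estimator is the load-bearing
reconstruction in the package and is validated three ways in the test
suite: mean estimated SE vs. empirical SD over 2000 simulated replicates,
agreement with a 500-draw nonparametric bootstrap on a single dataset, and
CI coverage against the design's known truth.

Intervals respect their ranges by transformation: logit for `w` and `l`
(degenerate estimates at 0 or 1 are flagged and reported as a collapsed
interval), `arctanh` for the net benefit with delta-method scale
`σ̂_nb/(1−NB̂²)` where `σ̂_nb² = σ̂_w² + σ̂_l² − 2σ̂₁₂`, and
`WO CI = exp(2·arctanh NB CI)` endpointwise — so NB and WO intervals are
consistent under their monotone link and share coverage exactly. The win
ratio is estimated directly as `exp{β̂ᵀ(z−z*)}` with a lognormal CI from
the β̂ sandwich. `|NB̂| = 1` pins the CI to the boundary and sets a flag.

**Stratified prediction (experimental).** No closed reference derivation
exists for the stratified variance; the package's own construction
makes the martingale pieces stratum-local (a subject's `dM̃` terms use its
own stratum's baseline and risk sets; only the requested stratum's baseline
enters the `Ĥ`/`ŝ⁽⁰⁾` terms) while the β̂ and γ̂ score pieces pool across
strata. One-stratum fits reduce exactly to the unstratified estimator; the
multi-stratum variance should be checked against a stratified bootstrap
before production use.

## Diagnostics

* **Subject win residuals** `M̂_i = (n−1)⁻¹ Σ_{j≠i} M_ij(∞; β̂)` — observed
  minus predicted win proportion per subject; they sum to zero exactly by
  antisymmetry. Plotted against a covariate they expose misspecified
  functional form (the tests reproduce a ceiling-effect scenario where a
  linear fit to a thresholded effect drives the upper-range residuals
  negative).
* **Score process** `Û(t) = (n choose 2)⁻¹ Σ_{i<j}(Z_i−Z_j)M_ij(t; β̂)`,
  which is 0 at t = 0 and returns to 0 at the maximum follow-up (the
  estimating equation). The default grid is the distinct observed
  first-event times plus the maximum follow-up — the latter is needed
  because a death occurring after a nonfatal event decides wins but is not
  a first event. The standardized version divides each component's
  unnormalized pairwise sum by `{Σ_{i<j}(ΔZ_k)² M_ij(∞)²}^{1/2}`; this
  scaling is a documented package choice made for visual trend detection
  only — every formal invariant is stated on the unstandardized process.
* **Schoenfeld residuals** for the Cox fit, summing to zero componentwise.

## Simulation design

Given `Z₁ ~ N(0,1)`, `Z₂ ~ N(−1,1)`, `Z₃ ~ Bernoulli(0.5)` (the stated
covariate law; the source's duplicated symbol is read as Z₂), outcomes
follow the Gumbel–Hougaard copula

    pr(D>s, T>t | Z) = exp[−{(e^{−β_DᵀZ}λ_D s)^κ + (e^{−β_TᵀZ}λ_H t)^κ}^{1/κ}]

with defaults `β_D = β_T = (0.5, 0, −0.5)`, `λ_D = 0.1`, `λ_H = 1`, `κ = 2`
(conditional Kendall τ = 1 − 1/κ = 0.5), censoring
`C ~ Unif[0.2,4] ∧ Exp(rate 0.02)` and maximum follow-up τ = 4. Sampling
uses the positive-stable frailty representation with Kanter's exact method
for stable index 1/κ; the tests verify the frailty's Laplace transform, the
exponential margins (Kolmogorov–Smirnov), the copula surface, and the
conditional Kendall τ at κ ∈ {1.25, 2, 4}. Nonfatal events after death are
never recorded (death terminates follow-up), and a nonfatal event enters
the long format only when it precedes `D ∧ C ∧ τ`.

Under equal coefficients the design satisfies the PW model with parameter β
*and* the Cox TFE model with `γ = −β`, `Λ₀(t) = (λ_D^κ + λ_H^κ)^{1/κ} t`,
giving closed-form truths: `tie(t) = exp{−(e^{−βᵀz}+e^{−βᵀz*})Λ₀(t)}`,
`w = μ(1−tie)`, and NB/WO/WR by algebra. The misspecified variant sets the
first coefficient to 0.5 for death but 0.1 for the nonfatal event, breaking
both models; there no closed form exists and `mc_true_win_prob` (uncensored
outcome pairs scored directly by the win rule) is the oracle — the
closed-form calculator refuses misspecified configurations explicitly.
Under these defaults the realized death rate is ≈24%; the realized nonfatal
event rate is ≈80%, a figure verified against an independent closed-form
calculation (`P(T<D∧u|Z) = λ_H^κ/(λ_D^κ+λ_H^κ)·(1−e^{−λ̃u})` averaged over
Z and C).

The operating-characteristics driver simulates replicates (one independent
seed stream per replicate spawned from a master seed, so any replicate is
reproducible in isolation), fits both models, predicts, and aggregates
Bias, empirical SD (SE), mean estimated SE (SEE) and CI coverage per
(pair, horizon), for w and the NB/WO contrasts. Replicates whose fit fails
are counted and dropped; more than 1% failures aborts the study. The
default is 500 replicates; the calibration tests use 2000 replicates of
n = 200 (binomial coverage error ≈ ±0.005), problem sizes chosen to resolve
the quantities being checked while keeping the suite fast.

## What the simulations do and do not show

The generator reproduces the structural features the method relies on —
prioritized bivariate event times with realistic dependence, independent
covariate-free censoring, proportional win fractions holding exactly in the
correct variant — so passing tests demonstrate internal validity:
consistency, variance calibration and interval coverage *when the models
hold*, and detectable diagnostics/bias when proportionality fails in the
specific differential-effect direction simulated. Real cohorts add features
the generator omits: covariate-dependent censoring, recurrent events with
K > 1 priority layers, discrete/tied event times beyond the tie convention
above, time-varying covariates, and model misspecification of arbitrary
form. Results here do not certify behavior under those conditions.

## Known limitations

* Influence-function variances are implemented for the Cox TFE model only;
  the point-prediction interface would accept any survival provider, but
  alternative TFE models (AFT, proportional odds) would need their own
  influence derivations.
* No simultaneous (uniform-in-t) confidence bands; all intervals are
  pointwise.
* The default win rule covers death over a single nonfatal event type;
  general win functions and left truncation are not implemented.
* The stratified variance is a reconstruction (see above) and is flagged
  experimental.
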