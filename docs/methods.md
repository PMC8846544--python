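# Methods

## Model overview

The package implements a mechanistic pipeline for androgen-deprivation
therapy (ADT) of hormone-sensitive prostate cancer, with serum PSA P(t)
(ng/ml) standing in for tumor burden.

**Tumor growth.** dP/dt = P·f(P). The central law is the log-power rate
f(P) = a(1+b ln(P/P_R))^γ for P > P_R and f = a below the detection
level P_R, which is continuous, defined for all P ≥ 0, super-exponential
above detection (blow-up in finite time), and needs a single autonomous
ODE. The unextended formula has a pole at P_c = P_R e^{−1/b} < P_R,
which the exponential extension below P_R removes. The comparison family
(exponential, Gompertz, logistic, generalized logistic with the
Greenspan preset γ = 2/3, a time-modulated law, and the two-equation
modulated-exponent law f = a(P/P_R)^{k(t)}, k̇ = λ) is implemented with
the same interface. All integration runs in y = ln(P/P_R), where every
law has a smooth right-hand side and most have closed-form solutions
(e.g. for the log-power law, (1+by)^{1−γ} is affine in t); the
closed forms are used by the generator and the population fitter, and
are tested against the adaptive integrator (LSODA, rtol 1e−8,
atol 1e−10 defaults; a configurable PSA cap, default 10⁶ ng/ml, converts
super-exponential blow-up into a reported time bracket).

**Pharmacokinetics of depot leuprolide.** Two formulations:

1. *Transit-compartment (mass-action)*: a depot feeding n transit
   compartments plus an immediate path into a cleared central
   compartment. Under β = k_tr = k₁ the chain has closed forms, and the
   quasi-steady central concentration L(t) = α e^{−k₁t}(k₂ +
   k₁^{n+1}tⁿ/n!)/d_L satisfies d_L·L = k₁Lₙ + k₂D exactly; its error
   against the true central compartment is O(k₁/d_L) and the package
   keeps the full linear system available (the oracle in the tests).
   Zero-order infusion (k₃·χ(t)) and the peripheral compartment (Q) are
   optional and default off.
2. *Microsphere diffusion*: drug diffuses out of polymer spheres with a
   perfect-sink boundary; the retained mass is
   M_in(t) = (6M₀/π²)Σ e^{−n²π²ρt}/n² with release rate ρ = Dc/R², and
   plasma drug follows dL/dt = Σ_doses k·(dose/M₀)·ψ(ρ_eff(t−t_d)) −
   d_L·L with ψ(x) = Σ e^{−π²n²x}. The naive ψ series needs O(x^{−1/2})
   terms as x → 0, so for x < 0.05 the exact Jacobi/Poisson identity
   ψ(x) = (1+2Σe^{−n²/x})/(2√(πx)) − 1/2 is used; likewise M_in uses the
   early-time square-root release law for ρt < 0.01. Both
   representations agree to machine precision at the switch points. The
   plasma convolution is evaluated by adaptive quadrature after the
   substitution s = v², which removes the integrable flux singularity at
   each dose time (this is also how evaluation *at* a dose time is
   defined: the right-limit, zero contribution). The ψ-argument rate is
   exposed both as ρ and as a_rel/M₀ because the release notation leaves
   that identification open; the two are interchangeable.

**Testosterone feedback.** LHRH (x) → LH (y) → TES (z) with negative
feedback h₁(z) = p₁/(1+b₁z); the two-variable reduction treats LH as
quasi-steady (its p₃ is an independent parameter, not literally
p₂p₃/d₂). The drug competes with LHRH in TES production:
h₃(x, L) = p₃x/(1+b₃(x+L)). Steady states are positive roots of
quadratics (a bracketed root-finder covers user-supplied monotone h₁,
h₃); the drugged TES steady state z̄_L decreases strictly in L with
z̄_∞ = 0, while x̄_L increases to p₁/d₁. The implicit-derivative
expression for dz̄_L/dL implemented here carries the b₁ factors obtained
by differentiating the steady-state quadratic; it reduces to the simpler
printed form when b₁ = 1. Local stability is verified numerically
(analytic Jacobians, eigenvalues, plus Routh–Hurwitz coefficients for
the 3×3 case); global convergence and dissipativity (the functional
U = x + d₁y/(2p₂) + d₁d₂z/(2p₂p₃) satisfies U̇ ≤ h₁(0) − αU for
α < min dᵢ/2) are checked by basin sampling rather than symbolic
Lyapunov constructions, which are out of scope.

**Treatment model and thresholds.** PSA couples to testosterone through
dP/dt = P f(P) + d_P (z − z̄₀ + g₁(r₁)) P with z̄₀ always derived from
the hormone submodel at L = 0. Resistance: ṙᵢ = βᵢL(1−rᵢ/lᵢ), rᵢ(0)=0,
with g₁(r) = a₁r boosting PSA and g₂(r) = L(a₂+e^r)/((a₂+1)e^r)
replacing L inside h₃ (g₂(0) = L, decreasing to L/(a₂+1)). Because the
(x, z) subsystem converges for constant L, the asymptotic PSA equation
is scalar with at most one positive (unstable) equilibrium
P̄ = P_R exp(((d_P(z̄₀−z̄_L)/a)^{1/γ}−1)/b), existing iff
a < d_P(z̄₀−z̄_L); ã = d_P z̄₀ is the dose-independent cure bound. With
the first mechanism saturated the deficit shrinks by a₁l₁ (the printed
alternative with an extra d_P factor is available behind
`extra_dp_factor=True`; the default is the reading consistent with the
threshold formula's structure). Fates are declared on the scalar
asymptotic flow: decay when P < 0.5·P_R, escape when P > 10⁶ ng/ml,
horizon 20 000 days by default (the statements are asymptotic, so the
separatrix tests use longer horizons and, for starts within the
numerical band around the equilibrium, the sign of the drift — exact for
a scalar autonomous flow). Time-varying L(t) from the PK module is
accepted as a simulator extension (ṙᵢ use instantaneous L), beyond the
constant-L analysis. Biochemical failure is operationalized as the first
time PSA exceeds `rise_factor` (default 2) times its running nadir.

## Synthetic-data generator

The generator emulates a pre-treatment ("watchful waiting") registry
cohort: 19 patients, 6–22 PSA measurements each (median ≈ 10), spans
388–5724 days, PSA from below detection to the 10³ ng/ml range. Visit
times are irregular (uniform within each patient's span, first visit at
t = 0, last at the span; evenly spaced sampling is available). Defaults,
chosen once as the study conditions:

| quantity | default | rationale |
|---|---|---|
| law | log-power, a = 5·10⁻⁴/day, b = 1, γ = 0.5 | median-span patients reach PSA ≈ 5 ng/ml and the longest spans ≈ 10³ ng/ml, matching the registry's range and median ≈ 2 |
| P_R | 1 ng/ml | detection level; never fitted |
| baselines | log-uniform 0.5–20 ng/ml | registry median 2 with values below detection present |
| random effects | lognormal on a, SD 0.4 (log scale) | moderate inter-patient spread; log scale guarantees positive rates |
| residual | SD 0.55 additive on ln(P/P_R) | the registry-scale log-MSE of the best-fitting law (≈ 0.31) implies a residual SD ≈ 0.56 |

Observations below P_R are floored at P_R and flagged censored; the
fitter drops them by default (optionally keeps them floored). A single
seed feeds a splittable per-patient stream, so patient k's record is
identical whether 5 or 500 patients are drawn.

What the generator does **not** emulate: treatment-phase PSA, assay
changes, visit-frequency dependence on disease state (informative
sampling), covariates, and any real registry values — so passing tests
demonstrate correctness of the machinery under the stated statistical
structure, not fidelity to any particular hospital's data.

## Population fitting (NMEM)

y_ij = ln(P_ij/P_R) is modelled as the law's log-scale solution from a
patient baseline y0_i plus N(0, σ²) noise; random parameters carry
lognormal patient effects φ_ik = β_k e^{b_ik}, b ~ N(0, ω_k²)
(diagonal covariance, default random set {a}). Baselines are flat-prior
nuisances integrated out with the random effects by a Laplace
approximation; anchoring on the noisy first observation instead was
found to bias the curvature parameters persistently (errors-in-variables
in the initial condition) and was rejected. Per-patient modes come from
a vectorized, warm-started damped Newton (numeric derivatives, batched
across patients; warm starts preserve patient-order invariance because
each inner problem is independent, and per-patient likelihood terms are
summed in sorted order so fits are bitwise order-invariant). The outer
optimization is multi-start Nelder–Mead (default 5 data-driven starts
from per-patient log-linear slopes; xatol 1e−4, fatol 1e−6, 400
iterations) over transformed fixed effects (logs; logit for the
log-power γ), log σ, and log ω. A first-order (FO) alternative
linearizes in b at 0 and evaluates the Gaussian marginal exactly.
Metrics: MSE and R² on the log scale against individual-mode
predictions; AIC = 2k + 2·NLL, BIC = k·ln n + 2·NLL with
k = fixed effects + random-effect variances + residual variance
(integrated baselines not counted) — the convention is embedded in every
report because external parameter-counting conventions differ. Model
selection ranks laws by AIC with BIC and parameter-count tie-breaks;
failed fits are recorded, not fatal. The selection experiments in the
acceptance harness use 2 starts per fit: AIC ranking is insensitive to
the additional starts (between-start NLL differences ≲ 0.05) and the
4-law × 20-replicate experiment then completes in a couple of minutes.

### Identifiability of the log-power law

At registry scale (19 patients, residual SD ≈ 0.55) the triple
(a, b, γ) is only weakly jointly identified: along the ridge
a(1+by)^γ ≈ (a b^γ) y^γ (large b) or ≈ a(1+bγy) (γ → 1) different
parameter triples produce nearly identical trajectories over the
observed log-PSA range, and the global maximum-likelihood estimate
frequently sits at the ridge ends with a *better* likelihood than the
generating values. The fitter is consistent — with ~150 patients a and
γ are recovered essentially exactly — so this is a property of the
design, not the estimator. Consequently parameter-recovery experiments
at n = 19 can show large relative errors on b and γ even though model
*selection* (AIC ranking of law families) remains reliable; users should
treat fitted b and γ from small cohorts as a fitted curve, not as
separately interpretable constants.

## Numerical choices

- Steady states: closed-form quadratic roots; Brent bracketing for
  generic monotone feedback functions (bracket doubled until sign
  change).
- ODEs: LSODA throughout (the PK chain and the log-power law above
  detection are stiffness-prone); rtol/atol are arguments everywhere,
  with tighter defaults (1e−10/1e−12) for the small hormone systems.
- Impulsive dosing: segment-wise integration with depot jumps at dose
  times; a grid point exactly at a dose time reports the post-impulse
  state.
- Mass balance: M_out is computed by quadrature of the release flux
  (independent of the M_in series), so the d_L = 0 conservation check is
  a genuine two-route comparison.
- Degenerate fits: zero-noise cohorts drive σ̂ → 0; with an active
  random effect the marginal likelihood is then flat along a
  compensation ridge, so exact-recovery checks use fixed-effects-only
  specifications (the smallest identifiable model). Random-effect SDs
  that collapse below 10⁻⁶ are reported as 0 with a warning.
- Fate horizons: 20 000 days by default, longer in separatrix tests;
  PSA cap 10⁶ ng/ml.

## Known limitations

- The delayed feedback system (explicit TES secretion delay) and
  receptor-occupancy pharmacodynamics are not modelled (out of scope).
- Global stability of the resistance subsystem is verified by multistart
  sampling, not proof.
- The FO method is implemented for a single random effect; multiple
  random effects use the slower generic per-patient mode search.
- Censored observations are excluded by default rather than contributing
  a censored-likelihood term; with low baselines this discards
  information below the detection level.
- Fitting real treatment-phase data (PK + resistance jointly) is not
  attempted; the fitting stage addresses the pre-treatment growth law
  only.
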