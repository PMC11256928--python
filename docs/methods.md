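# Methods

## Problem setting

An XL-MS/MS search engine assigns every experimental spectrum a ranked
list of candidate peptide pairs with scores. Identification accepts the
top-ranked PSM when its score exceeds a threshold τ; the false discovery
rate (FDR) is the expected fraction of accepted top PSMs whose peptide
pair is not the generating one. `xlfdr` estimates this FDR from the score
distributions alone (decoy-free), by exploiting the fact that the top two
scores of a spectrum carry complementary information about the latent
match classes.

## Score extraction

From a ranked candidate table the package keeps, per spectrum, the top
score s1 and second score s2. If the top two candidates share the same
(sorted) peptide pair and differ only in the cross-link residue position,
the second is redundant — the third candidate, if present, is promoted to
the second slot. Spectra with a single eligible candidate get a missing
s2; the fraction of such spectra, v_Φ, is carried as a constant. Scores
are used on the engine's native scale.

## The two-sample mixture

Latent classes: C (correct), J1/J2 (best and second-best partially
incorrect), I1/I2 (best and second-best incorrect), each with a
skew-normal (SN) score distribution θ_Y = (μ_Y, σ_Y, λ_Y). The top score
can only be C, J1 or I1; the second score can be any of the five. The two
mixtures share θ_C, θ_J1, θ_I1, which is what lets the second-ranked
sample stabilize the placement of the top-score components. The
observed-data log-likelihood sums the three-component mixture over all s1
and the five-component mixture over the observed s2 only; missingness
enters the estimation solely through v_Φ in the weight constraints. The
dependence between s1 and s2 of the same spectrum is not modelled — a
known approximation of this family of models.

Skew-normal machinery uses the alternate parametrization
Δ = σδ, Γ = σ² − Δ², δ = λ/√(1+λ²), under which S = μ + ΔT + √Γ·U with
T a positive truncated standard normal and U standard normal. The CDF is
Φ(z) − 2·T(z, λ) with Owen's T from `scipy.special.owens_t`; the survival
function is computed as Φ(−z) + 2·T(z, λ) to stay accurate in the right
tail, where FDR thresholds live. The conditional moments of T given an
observation (ξ1, ξ2) use the Mills ratio evaluated through `log_ndtr`,
which is stable arbitrarily far into the tail. The mode, needed by the
density constraints, has no closed form; it is computed as the unique
root of the standardized log-density derivative −z + λ·φ(λz)/Φ(λz)
(bracketed Brent / safeguarded Newton in the compiled kernel, tolerance
1e-12), which for a unimodal density is equivalent to, and tighter than,
bounded scalar maximization.

## Constraints

**Weights.** Eight inequalities couple w and v (set "B"), derived from
the fact that the top and second score of one spectrum cannot come from
the same candidate, e.g. w_C ≤ v′_J1 + v′_I1 + v_Φ with
v′_Y = (1 − v_Φ)·v_Y. At v_Φ = 0 they reduce to the no-missingness form
(set "A"), which is exposed for testing. Comparisons use a 1e-12
tolerance to avoid chatter at equality.

**Density dominance.** The fit enforces the chain
f_C ≻ f_J1 ≻ f_J2 ≻ f_I1 ≻ f_I2, where f ≻ g requires mode(f) > mode(g),
f above g right of f's mode, and g above f left of g's mode. The two
"for all x" conditions are evaluated on a dense grid over a bounded
window extending 4·max(σ_f, σ_g) past each mode. The window is a
deliberate design choice: enforced literally out to infinity, the
conditions reduce to inequalities between quadratic tail-decay
coefficients under which two components of equal shape magnitude can only
dominate with exactly equal scales — a measure-zero event that the random
initialization (which draws scales independently) would never satisfy.
The bounded window covers everything but ~1e-4 of each component's mass,
i.e. every region the likelihood or the threshold inversion can see.

**Binary-search repair.** Every candidate parameter value (μ, Δ or Γ,
updated in that order) that violates a dominance pair is pulled back by
bisection along the segment to the previous (feasible) value, stopping
within 1e-9 of the segment length from the feasibility boundary, and the
committed value is backed off marginally from the boundary so it survives
parametrization round-trips; repaired values feed the subsequent updates
of the same component. A previously committed point that re-evaluates as
marginally infeasible (ulp drift) is treated as on-the-boundary and left
in place rather than declared a contract violation.

## The constrained ECM iteration

1. **E-step** — posterior responsibilities of every score for every
   component, and the truncated-normal moments ξ1, ξ2, all under the
   current parameters (log-sum-exp throughout).
2. **Conditional M-steps** — per component (C, J1, J2, I1, I2 in order),
   the closed-form updates μ̈ → Δ̈ → Γ̈, each repaired as above. Shared
   components pool both samples; J2 and I2 see the second sample only.
   A component whose responsibility mass falls below 1e-10 is frozen for
   the iteration.
3. **Weight M-step** — maximize the weight part of the Q-function under
   the simplex equalities and constraint set B via the KKT stationarity
   system. The unconstrained solution (responsibility averages) is used
   when feasible. Otherwise a greedy active-set search activates violated
   inequalities singly, then in pairs, triples, …; each active set is
   solved by a damped root-finder (hybr, analytic Jacobian) with an
   equality-constrained SLSQP fallback, and a candidate is accepted only
   if the normalized stationarity residual is below 1e-8, the weights are
   strictly positive and feasible, complementary slackness holds, and the
   active multipliers are non-negative — with a concave objective and
   linear constraints, dual feasibility certifies the global optimum. A
   last-resort full inequality-constrained solve covers pathological
   collapsed-responsibility instances; if even that fails inside a fit
   iteration the previous weights (still feasible, since set B depends
   only on the constant v_Φ) are kept for the iteration.

Convergence: relative log-likelihood change |ΔL|/(|L|+1) < tol
(default 1e-8) or `max_iter` (default 1000) iterations. With active
inequality constraints the weight update is not guaranteed monotone in
the likelihood; in practice the trace increases, and the final
log-likelihood is asserted to be at least the initial one.

## Initialization and restarts

Per restart: a normal fit (μ̂, σ̂) to the top scores; five draws from
N(μ̂, σ̂) sorted descending become the component locations (matching the
dominance ordering); σ_Y ~ U[σ̂/4, σ̂]; |λ_Y| ~ U[1/λ0, λ0] with
λ0 ∈ {1, 2, 5} (degenerate at 1 when λ0 = 1); signs λ_C > 0,
λ_J2, λ_I1, λ_I2 < 0, and λ_J1 tried with both signs — six
initializations per round, resampled (up to 1000 times) until the density
chain holds; the weight constraints are not required of the initial
point. Weights start at w = (1/3, 1/3, 1/3) and
v = (0.001, 0.999/4 ×4). The default budget is 240 restarts (40 rounds).

The likelihood surface is genuinely multimodal, with distinct local
optima often within a few nats of each other, so restart budget is the
dominant cost. The driver therefore supports *screening*: every
initialization runs a short burn (default 60 iterations) on a fixed
5000-spectrum subsample — ranking basins does not need the full data —
and only the top few (default 8) continue to convergence on the full
data; the winner is always polished at a 10× tighter tolerance with a
doubled iteration budget. Screening is off by default (pure multi-restart
behaviour); the test-suite fits use 48 screened restarts, which costs
less than 24 full runs and finds the dominant basin more reliably.
`init_model` adds a caller-supplied initialization (used to warm-start
bootstrap replicates). All randomness flows from a single seed through
`numpy.random.SeedSequence`, so fits are bit-reproducible.

The one-sample variant fits S1 alone as a three-component mixture with
chain C ≻ J1 ≻ I1, unconstrained weight updates, and the same
initialization scheme.

## FDR estimation

The model-based estimate at τ is the ratio of incorrect-component to
total survival mass of the S1 mixture. Thresholds invert the *monotone
envelope* of the estimate on a 4096-point grid refined by bisection to
1e-6 of the score range: the raw curve can be non-monotone deep in the
right tail where all survivals underflow. −∞ is returned when the FDR is
below α everywhere, +∞ when α is unattainable. The TDA baseline counts
TT/TD/DD labels above τ and returns (TD − DD)/TT unclamped with an
`over_one` flag, exposing rather than hiding the >1 pathology; note the
estimator is unbiased for the true FDR only with an equal-size decoy
database (decoy probability 1/2 per peptide).

## Synthetic data

Two deliberately different generators provide ground-truth labels:

* **Mixture-faithful** — draws (s1, s2) exactly from the two-sample
  mixture; truth is inside the model family, so it measures parameter
  recovery.
* **Competition** — simulates the latent contest: a correct candidate
  present with probability ρ, ordered pairs (j1 ≥ j2) and (i1 ≥ i2)
  (rejection sampling with an exact inverse-CDF fallback for deep-tail
  cases), top score = best present candidate, second score = the
  structural runner-up, then s2 dropped with probability
  expit(intercept − slope·s1), concentrating missingness in the left
  tail. Conditioned on winning, the winner's law is *not* the component
  SN — the mixture is an approximation of this process, which is exactly
  why calibration (not recovery) is tested on it.

The reference scenario places the five components at
C(40, 5, +2), J1(30, 5, −2), J2(23.5, 5, −2.5), I1(17, 5.5, −2.5),
I2(10, 5.5, −3) on a typical search-score scale, with w = (.15, .25, .60),
v = (.01, .19, .18, .22, .40) and v_Φ = 0.3. The adjacent modes sit
1.2–2σ apart — the separation real score histograms show, and the regime
in which the five-component mixture is statistically identifiable; at
substantially heavier overlap the maximum-likelihood optimum genuinely
differs from the generating values and no correct fitter could recover
them. vJ2 is commensurate with wJ1 because when a partial match tops the
list, its own second partial match is the typical runner-up. Neither
generator reproduces engine-specific score discreteness, the s1–s2
dependence within a spectrum, or heterogeneous per-run score scales, so
passing tests demonstrate correctness of the estimator under the model's
assumptions, not performance on any particular instrument's data.

## Test-scale choices

The heavy checks run at n = 20 000 spectra. Parameter recovery uses five
datasets with 48 screened restarts and reports seed-averaged errors: the
truth-started MLE itself deviates from the generating values by up to
~0.07σ per seed from sampling alone, so per-seed bounds would measure
seed luck rather than estimator quality. FDR calibration uses five
competition datasets (24 screened restarts). The bootstrap study runs 20
independent datasets, B = 20 spectrum-level resamples each, with the
full-data fit warm-started at the generating model and replicates
warm-started at the full-data fit — the study targets the bootstrap
interval's coverage of the true threshold, not basin discovery, which the
recovery test already exercises.

## Known limitations

* The s1–s2 dependence within a spectrum is unmodelled; strong
  dependence (e.g. chimeric spectra) biases the second-sample components.
* Weight updates under active constraints can in principle decrease the
  likelihood; only the overall increase is guaranteed empirically.
* The dominance conditions are enforced on a bounded window (see above);
  behaviour beyond ~4σ past the extreme modes is unconstrained.
* SN shape parameters near λ = 0 are weakly identified (singular
  information), so canonical-parameter estimates for nearly symmetric
  components carry large variance even when the fitted density is
  accurate.
* TDA comparisons assume exchangeable decoys and an equal-size decoy
  database.
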