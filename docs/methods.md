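# Methods

## Model

The population is closed (births equal deaths at per-capita rate `mu`, so
N is constant) and randomly mixing. Individuals are never-obese (S), obese
(I) or ex-obese (R). The force of infection is additive,
`lambda(t) = beta*I(t) + epsilon`: a contagious hazard proportional to
prevalence and a constant non-contagious hazard capturing genetics, diet
and lifestyle, assumed marginally independent of the contagious route.
Obese individuals recover at rate `gamma`; ex-obese individuals are
non-contagious but relapse at `sigma` times the never-obese hazard.

Two intervention variants rescale parts of the flow structure. Primary
prevention multiplies both hazards acting on never-obese individuals by
`alpha` (the relapse hazard is untouched). Secondary prevention multiplies
both the recovery rate and the relapse term by the same factor `kappa`,
reflecting a program directed at people who have been obese at least once.
Both reduce exactly to the baseline system at factor one, so a single
right-hand side parameterised by `(alpha, kappa)` implements all three
systems. One consequence worth stating plainly: because `kappa` scales
recovery and relapse *together*, pushing `kappa` below 1 slows recovery and
raises the equilibrium prevalence — the beneficial direction for secondary
prevention is `kappa > 1` ("enhanced" programs). The intervention-comparison
sweep therefore reports both curves over the full factor range rather than
imposing an ordering.

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| N | population size | 100 000 | individuals |
| 1/mu | life expectancy at birth | 69.4 | years |
| beta | transmission coefficient | 2.96e-7 | per individual per year |
| epsilon | non-contagious hazard | 0.012 | 1/year |
| sigma | relative relapse hazard of ex-obese | 8.0 | — |
| 1/gamma | mean duration of an obese episode | 35.8 | years |

The defaults are the published empirical calibration this model family
uses: life expectancy as a weighted world average, `sigma` and the
household attack proportions from weight-regain and household studies,
`epsilon` and `1/gamma` from longitudinal cohort data. The calibrated
`beta` range 1.99e-7–4.33e-7 comes from household SAPs 0.135–0.254 with
m = 3 (see below); 2.96e-7 is the published baseline value and is used
verbatim rather than re-derived.

## Equilibria and stability

Setting derivatives to zero and holding `lambda` fixed makes the system
linear; eliminating S and R gives the closed-form stationary prevalence

    i(lambda) = lambda*mu*(sigma*lambda+mu)
                / [(lambda+mu)((mu+gamma)(sigma*lambda+mu) - sigma*lambda*gamma)]

(the bracket simplifies to `mu*(sigma*lambda + mu + gamma)`, hence is
strictly positive for `mu > 0`). Equilibria are roots of
`g(lambda) = beta*N*i(lambda) + epsilon - lambda` on `[0, beta*N+epsilon]`.
Roots are isolated by a dense uniform pre-scan (10 000 intervals,
vectorised) and polished by Brent's method to 1e-12 relative tolerance in
`lambda`; `lambda = 0` is an exact root precisely when `epsilon = 0` and is
handled exactly, with the scan started just off zero so interior roots near
the origin are still captured. The dense pre-scan is what makes multi-root
capture robust in the backward-bifurcation window; tangency (double) roots
exactly at a fold can in principle be missed, which only affects
measure-zero parameter points. With `epsilon > 0` the model has a unique
non-negative equilibrium throughout the parameter neighbourhood of the
defaults. Under interventions the same reduction holds with the modified
closed form

    i(lambda; alpha, kappa) = alpha*lambda*mu*(kappa*sigma*lambda+mu)
        / [(alpha*lambda+mu)((mu+kappa*gamma)(kappa*sigma*lambda+mu)
                             - kappa^2*sigma*lambda*gamma)].

Stability is classified on the two-dimensional (S, I) system with
`R = N - S - I` substituted, which removes the zero eigenvalue the
conservation law forces on the three-dimensional Jacobian. The Jacobian is
analytic; eigenvalues with `|Re| < 1e-10` are reported as "marginal" rather
than forced into a stable/unstable call. `mu = 0` is rejected at parameter
validation: without demographic turnover the stationary age distribution
and the equilibrium reduction both degenerate.

With `epsilon = 0` and `sigma = 8` the relapse amplification produces a
backward bifurcation: between the fold near `beta = 2.94e-7` and the
`R0 = 1` threshold at `beta = (gamma+mu)/N = 4.23e-7` the obesity-free
state and an upper endemic branch are simultaneously stable, separated by
an unstable branch. "Headline" prevalences in sweeps are therefore defined
by reachability from the obesity-free start (N, 0, 0): the obesity-free
branch while it is stable, the stable endemic branch otherwise, with all
branches retained in the output alongside their stability flags.

## Time-domain integration

LSODA with relative tolerance 1e-8 and absolute tolerance 1e-10*N, dense
output sampled on a uniform grid (default 0.5 y). The contract was checked
up to `sigma` ten times the default. Conservation (`|S+I+R-N| <= 1e-6*N`)
and non-negativity (floor `-1e-9*N`) are verified on every trajectory and
violations raise an integration error; trajectories are never renormalised.
The default 1000-year horizon comfortably covers the ~200-year settling
time of the baseline system. Settling time is defined (no canonical
definition exists for this quantity) as the first output-grid time from
which the sup-norm distance to equilibrium, relative to N, stays below
0.005 through the horizon, rounded to the nearest year; at the defaults
this gives 159 y.

## Age-structured risk

At equilibrium the age profile of a birth cohort obeys the linear system
with constant coefficients given by fixing `lambda*`; there is no feedback
from age structure to transmission. The profile is integrated with the same
adaptive contract (rtol 1e-10) on a default grid of 0–110 y at 0.1 y; tests
verify it against the matrix-exponential solution and the closed form
`X(a) = Nc(0) exp(-(lambda*+mu)a)`. The cohort inflow is `Nc(0) = mu*N`,
and exponential survival gives `Nc(a) = Nc(0) e^{-mu a}`, integrating back
to N over all ages.

Risk curves are normalised by `Nc(0)` ("risk at birth") by default — the
three curves then do not sum to one at positive ages, by construction,
because of mortality; normalisation by the surviving cohort `Nc(a)` is
available as an option. The peak-risk age maximises `Y(a)/Nc(0)` using an
exact eigen-decomposition propagator: a 0.5-y coarse grid brackets the
maximum (first maximum wins on ties) and bounded scalar minimisation
refines it to 1e-3 y, well inside the 0.05-y agreement required against a
brute-force grid. The exponential-survival assumption is also why the
equilibrium prevalence (~61%) exceeds currently observed prevalences: the
model population carries no age-specific mortality or hazards.

## Household calibration and the synthetic generator

Calibration uses `SAP = R0/(R0+m)` (single index case, m
susceptible-and-exposed members) inverted to `R0 = m*SAP/(1-SAP)`, then
`beta = R0*(gamma+mu)/N`. The `R0` formula is derived for the
`epsilon = 0` system; household observation windows are short relative to
the life course, so the non-contagious hazard is negligible there. The
conversion is deliberately not gated on `epsilon`, and no threshold claim
is attached to `R0 = 1` for the full model (relapse and `epsilon > 0`
break the threshold property).

The synthetic generator draws, per household, an index "infectious" sojourn
`T ~ Exp(gamma+mu)` (recovery competing with death, matching the
denominator of `R0`) and a `Binomial(m, 1-e^{-bT})` count of secondary
onsets with `b = R0*(gamma+mu)/m`. Marginalising over T gives per-susceptible
infection probability exactly `R0/(R0+m)`, so the estimator chain is
consistent by construction and is verified by parameter recovery (5% at
1e5 households across the calibrated `beta` range). Transmission is
first-generation only — that is what the secondary-attack-proportion
definition measures, and it is what makes the identity exact; no tertiary
chains, no inference of `sigma` or `gamma` from household data.

What the generator does *not* emulate: household contact-network structure,
covariates, varying household sizes, reporting error, or time-varying
infectiousness. Passing recovery tests therefore shows the estimator chain
is correct under the model's own sampling law, not that real household data
satisfy that law. One statistical consequence is real and documented: the m
susceptibles of a household share the index sojourn, so pooled Bernoulli
trials are positively correlated and the Wilson interval on the pooled SAP
is mildly anti-conservative for m > 1 (measured coverage ~0.89 at nominal
0.95 with m = 3); at m = 1 coverage is nominal. The interval is retained
(the dependence is weak and the point estimate unbiased), and tests pin
both behaviours.

## Scenario program and the delayed-sequel convolution

Sweeps express interventions as multipliers on baseline values (reduction r
is multiplier 1-r; multipliers above 1 are allowed where worsening is
meaningful). Every sweep cell is an independent equilibrium solve; tests
cross-check cells against a million-point dense-scan oracle. The
transmissibility sweep runs at non-contagious-hazard multipliers
{0, 0.1, 1, 10} and the duration sweep at relapse multipliers {0.1, 1, 10};
grids of 81 beta points on [0, 8e-7] and 70 duration points on [1, 70] y
resolve the abrupt prevalence rise without noticeable cost. The univariate
and combined intervention sweeps run at both calibrated `beta` endpoints
(1.99e-7 and 4.33e-7): at the low endpoint reducing `epsilon` is the most
effective single intervention; at the high endpoint it is the least.

The delayed-sequel risk (e.g. heart attack after obesity onset) is
`w(a) = p * ∫ f(s)(1-x(a-s)) ds` with `1-x(u) = 1-e^{-(lambda*+mu)u}` for
`u >= 0` and zero otherwise — the cohort-survival interpretation of "ever
obese by age a"; individual obesity-history alternatives are out of scope.
The delay density f is configurable (gamma by default with user-set
shape/scale, since no canonical delay law exists; exponential and point
mass provided); densities are checked to integrate to one (1e-6) and
quadrature is adaptive with 1e-8 absolute tolerance. `w` is non-decreasing
in age and bounded by p.

CSV outputs are RFC-4180 with '#'-prefixed metadata headers echoing the
full parameter set, shortest round-trip float formatting, and bit-identical
regeneration from a fixed parameter set (note that exact re-parsing
requires a round-trip float parser, e.g. pandas `float_precision="round_trip"`).

## Known limitations

- Random mixing; no contact-network heterogeneity, which would shift
  epidemic thresholds.
- `epsilon`, `mu`, contact rates are age- and time-constant; exponential
  survival inflates equilibrium prevalence relative to observed values.
- `beta` and `epsilon` are treated as independent, which likely
  overestimates the effect of primary prevention.
- No demographic stochasticity at population level; the only stochastic
  component is the household generator.
- No cost-effectiveness layer; prevalence is the sole outcome scale.
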