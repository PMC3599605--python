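# obesim

Obesity spreads through social networks as well as arising spontaneously.
`obesim` implements a compartmental model of that dual-route epidemic for
epidemiologists and modellers who want to compare obesity-control programs
on a common, population-level scale: never-obese (S), obese (I) and
ex-obese (R) individuals in a closed, randomly mixing population of size N,
with force of infection

```
lambda(t) = beta * I(t) + epsilon
```

(contagious + non-contagious hazards, additive), relapse among ex-obese at
`sigma * lambda` (sigma > 1: ex-obese are more prone to weight regain),
recovery at rate `gamma`, and demographic turnover at rate `mu`:

```
dS/dt = mu*N - lambda*S - mu*S
dI/dt = lambda*S + sigma*lambda*R - (mu + gamma)*I
dR/dt = gamma*I - sigma*lambda*R - mu*R
```

The package provides:

- **Dynamics** — adaptive integration of the baseline system and of its two
  intervention variants: primary prevention (hazards on never-obese scaled
  by `alpha`) and secondary prevention (recovery and relapse scaled by
  `kappa`).
- **Equilibria** — all stationary states via a scalar reduction
  `g(lambda) = beta*N*i(lambda) + epsilon - lambda`, with analytic Jacobian
  stability classification and bifurcation scans; relapse (`sigma > 1`)
  produces a backward bifurcation at `epsilon = 0`, i.e. a stable endemic
  state below the R0 = 1 threshold.
- **Age-specific risk** — the stationary age-structured profile at fixed
  `lambda*`, the cumulative risk
  `q(a) = lambda*/(lambda*+mu) * (1 - exp(-(lambda*+mu)a))`, the lifetime
  risk `lambda*/(lambda*+mu)` and the peak-risk age.
- **Calibration** — household secondary attack proportions to the basic
  reproduction number via `SAP = R0/(R0+m)` and to the transmission
  coefficient via `R0 = beta*N/(gamma+mu)`, plus a stochastic household
  outbreak simulator whose marginal law reproduces the SAP relation exactly,
  so the whole chain is testable by parameter recovery.
- **Scenario tables** — sensitivity sweeps, primary-vs-secondary prevention
  comparison, a delayed-sequel risk convolution
  `w(a) = p * ∫ f(s) (1 - x(a-s)) ds`, and deterministic CSV export.

## Worked example

```python
from obesim import (ModelParams, State, integrate, solve_equilibria,
                    peak_obesity_age, lifetime_risk, sap_to_beta)

params = ModelParams()          # N=100000, 1/mu=69.4 y, beta=2.96e-7/y,
                                # epsilon=0.012/y, sigma=8.0, 1/gamma=35.8 y
eq = solve_equilibria(params)[0]
print(f"equilibrium prevalence: {eq.I_star / params.N:.1%}")
print(f"lambda* = {eq.lambda_star:.4f}/year, {eq.classification}")

traj = integrate(State(S=params.N, I=0.0, R=0.0), 1000.0, params)
print(f"prevalence after 1000 y: {traj.prevalence[-1]:.1%}")

print(f"peak-risk age: {peak_obesity_age(eq.lambda_star, params):.1f} y")
print(f"lifetime risk: {lifetime_risk(eq.lambda_star, params.mu):.3f}")
print(f"beta from SAP=0.135, m=3: {sap_to_beta(0.135, 3, params):.3g}")
```

prints

```
equilibrium prevalence: 60.9%
lambda* = 0.0300/year, stable
prevalence after 1000 y: 60.9%
peak-risk age: 37.0 y
lifetime risk: 0.676
beta from SAP=0.135, m=3: 1.98e-07
```

At the baseline parameter values the system settles (from an obesity-free
start) at about 61% obesity prevalence after roughly two centuries; the
stationary birth-cohort risk of being obese peaks at age 37, and roughly
two thirds of a birth cohort experience obesity at least once. A household
secondary attack proportion of 0.135 with three exposed members calibrates
the transmission coefficient to about 2.0e-7 per individual per year.

The same analyses are scriptable from a shell:

```
obesim equilibrium
obesim calibrate --sap 0.254 --m 3
obesim households --r0 1.0 --n 1000 --seed 7 --out hh.csv
obesim figures --out-dir tables/
```

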