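# pwlid — stochastic system identification with piecewise-linear rates

`pwlid` identifies production, degradation and growth rate functions of
one-dimensional gene-expression dynamics **without choosing a kinetic model
a priori**. Instead of committing to constant, linear or Michaelis–Menten
kinetics, every rate is a general-purpose piecewise-linear set-point curve
that can approximate any continuous rate law — including non-monotonous
profiles whose minimum at the population mode is the hallmark of
noise-driven regulation. The package is aimed at systems biologists who
want to know *which* regulation types are consistent with their data
(flow-cytometry histograms, metabolic-labelling measurements, or
single-cell tracking), rather than the single best fit of a preselected
model.

## The model

Cells carry `n = 0…N` molecules and progress through `k = 5` cell-cycle
phases with relative volume `v_i = 1 + (i−1)/(k−1)`. The frequency table
`F(n, i)` of cells per state obeys the population rate equation

```
dF(n,i)/dt = [Eₙ⁻¹ − 1] P(n,i) F(n,i) + [Eₙ⁺¹ − 1] D(n,i) F(n,i) − G(n,i) F(n,i)
             + { 2 Σₘ G(m,k) b(n|m,½) F(m,k)   (i = 1, division inflow)
               { G(n,i−1) F(n,i−1)             (i = 2…k, phase progression)
```

where `Eₙˢ` shifts the molecule number, `R(n,i) = R(⌊n/v_i⌋)` corrects all
rates for cellular volume, and `b(n|m,½)` is the symmetric binomial
partitioning of molecules between daughters. Production and degradation
are piecewise-linear curves with three y-set points each (capped at
12 h⁻¹; degradation anchored at `D(0) = 0`), growth is a non-decreasing
curve capped at `ln 2 / 2` h⁻¹ (2-h minimum doubling time). With zero
growth the equation reduces to a one-dimensional chemical master equation
whose stationary law has the detailed-balance closed form
`π(n) ∝ Π P(j−1)/D(j)` — used throughout as an independent oracle for the
Euler-forward integrator.

On top of this core, the package provides

* **Fokker–Planck noise decomposition** of the marginal density into
  deterministic (`A = P − D`), regulated-noise (gradients of
  `B = P + D`) and diffusion terms, with classification into
  noise-driven, noise-regulation-dominated and deterministic-dominated
  regimes;
* **NDO (noise-driven optimisation)** — random-restart stochastic search
  that perturbs the lowest-error parameters found so far with a noise
  scale that shrinks as the fit improves, mapping entire feasible
  parameter regions on a 16-bins-per-dimension grid (plus a local
  Hessian sensitivity analysis);
* **synthetic data generators**: 1-D histograms, 2-D labelled/total
  molecule distributions from an extended rate equation (4sU metabolic
  labelling), and exact continuous-time single-cell event trajectories
  via thinning, with frame-sampled degradation;
* **six identification error functionals** (`Freq1D`, `Freq2D`,
  `RatesPAV`, `RatesSCTid`, `RatesSCT`, `LogLikeSCT`) and a comparison
  protocol with cross-method scaling, error-vs-distance profiles and
  parameter spreads;
* **trajectory analysis** for gene-wise production/degradation/expression
  time courses: smoothing splines, correlation statistics with exhaustive
  permutation nulls (all 5040 orderings of 7 time points), trend
  classification, complete-linkage clustering at correlation distance
  0.15, and within-cluster variation;
* **virtual treatment experiments** that quantify how the same dose moves
  the expression distribution under different regulation types.

## Worked example

The classical birth–death special case (constant production `α`, linear
degradation `λn`, mean `ν = α/λ`) and a production treatment calibrated
to a target post-treatment mean:

```python
import numpy as np
from pwlid import (birth_death_system, CellCycleConfig, equilibrate,
                   marginalise, TreatmentSpec, run_treatment)
from pwlid.population import distribution_moments

cfg = CellCycleConfig()          # k = 5 phases, 1-minute Euler steps
rs = birth_death_system(alpha=6.0, lam=1.0, N=60)
ground = equilibrate(rs, cfg)
mean, sd = distribution_moments(marginalise(ground))
print(f"ground state: mean = {mean:.1f}, sd = {sd:.1f}")

out = run_treatment(rs, TreatmentSpec("production", target_mean=10.6), cfg)
print(f"dose: production x {out.multiplier:.2f}")
print(f"treated state: mean = {out.mean_after:.1f}, sd = {out.sd_after:.1f}")
print(f"mean shift: +{out.mean_shift_pct:.0f}%")
```

prints

```
ground state: mean = 6.0, sd = 2.4
dose: production x 1.77
treated state: mean = 10.6, sd = 3.3
mean shift: +77%
```

The ground state is the truncated Poisson(6) (sd √6 ≈ 2.4); raising the
mean to 10.6 requires a 77 % boost and widens the distribution to
sd 3.3. Under crowding-type regulation (`pwlid.crowding_system()`,
production down-regulated with `n`, constant degradation for `n ≥ 1`)
the identical dose moves the mean far less and leaves the width
essentially unchanged — which is why it matters *which* feasible
regulation type the identification selects.

A command-line interface mirrors the main workflows
(`pwlid simulate | fit | compare | labelling | treat | synth`); every run
writes a metadata file with the config echo and seed so stochastic
outputs are exactly reproducible.

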