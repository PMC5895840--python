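# Methods

## Rate model

All rates are piecewise-linear set-point curves: linear interpolation
between strictly increasing (x, y) set points, constant extrapolation
right of the last point. Production and degradation carry three free
y-set points each and are capped at 12 events/h; degradation has an
implicit anchor at (0, 0) (a cell without molecules cannot lose one),
production is held constant left of its first set point. Growth is
non-decreasing with two free y-set points, the third fixed at the cap
ln 2 / 2 per hour (2-h minimum doubling time). The induction curve I(t)
∈ [0, 1] over time has anchors I(0) = 0 and I(t) = 1 beyond its third
time set point (defaults 0.5, 2, 5 h, the measurement grid of a
medium-change experiment), leaving two free parameters; it blends
production and degradation between a fast-proliferation and an
activated rate system, R(n, t) = R_f(n)[1 − I(t)] + R_s(n) I(t), while
growth switches to the activated profile instantly at the medium change
(proliferation responds to the medium directly, not through the delayed
induction intermediates).

x-set points are fixed, not fitted. The default places them at N/6,
N/2 and 5N/6 (rounded): equidistant interior positions give the y-set
points comparable influence on the curve, which keeps the 0/1-scaled
parameter space isotropic for the optimiser. Scaled parameters divide
each y-value by its curve's cap, so identification always works on the
unit hypercube, with names PY1…PY3, DY1…DY3, GY1, GY2, IY1, IY2.
Monotonicity of growth is a constraint, not a repair: unscaling a
vector with GY1 > GY2 is a validation error rather than a silent sort.

## Population dynamics

The frequency table F(n, i) over molecule number n = 0…N and cell-cycle
phase i = 1…k (k = 5 throughout) evolves by Euler-forward integration
with a 1-minute step: production moves mass n → n+1, degradation
n → n−1, growth advances phases, and phase-k mass divides with factor 2
into phase 1 with binomially partitioned molecules (a deterministic
floor/ceil halving mode is available; the two give equilibrium means
differing by under 2 %). All rates are looked up at the dilution-
corrected concentration ⌊n/v_i⌋ with v_i = 1 + (i−1)/(k−1).

Boundaries: no mass leaves [0, N]. Production outflow from n = N is
suppressed (reflecting), so zero-growth dynamics conserve the cell
count exactly; analyses keep the distributional mass in the lower two
thirds of the range so this boundary is never materially occupied.
Strict positivity of an Euler step is enforced up to a 1e-12 relative
tolerance: uncapped linear degradation (the birth-death special case)
formally exceeds the 1/dt outflow limit in states whose occupancy is
~1e-30, and clipping those to zero is numerically indistinguishable
from the exact dynamics, while material mass loss still raises a
step-size error.

Equilibration integrates until the max-norm change per step falls below
1e-10 (1e-12 where an oracle comparison needs tighter convergence) with
a 72-h default horizon corresponding to three days of culture; fixed
points of the Euler map coincide with the exact stationary laws, so the
step size does not bias equilibria. For zero growth the dynamics are a
birth-death chain and the closed form π(n) ∝ Π P(j−1)/D(j) (computed in
log space) serves as an independent oracle; the integrator agrees with
it to better than 1e-6 in L1 on N ≤ 30 systems. A chain whose interior
degradation vanishes while production feeds it has absorbing structure
and no detailed-balance law; this is reported as a validation error,
and fitting objectives treat such candidates as maximal-error.

Population summaries weight the dilution-corrected rates by the
occupation probabilities p(n, i): averages P̄, D̄, slope averages dP̄,
dD̄ (central differences of the rate tables), Ā = P̄ − D̄ (which drives
the total molecule count, dT/dt = M·Ā, verified by finite differences
in the tests), and the population-weighted P–D correlation computed per
phase with weights p(n, i) and then averaged across phases weighted by
phase occupancy.

## Fokker–Planck decomposition

The marginal density p(x) is decomposed diagnostically (never
integrated forward) into a deterministic term ∂ₓ(−A p), a regulated-
noise term ∂ₓ(B′ p) − ½B″p, and a diffusion term (B/2) p″, with
A = P − D and B = P + D evaluated directly on the molecule grid (the
decomposition characterises the regulation, not the cell-cycle
machinery). All derivatives are central differences with unit spacing;
entries where a centred stencil does not fit are excluded rather than
approximated one-sidedly, and the reported averages are Σ p(x)|term(x)|
over the remaining interior states of the marginal p(n) (the 1-D
density the decomposition is stated for). Dynamics are classified
noise-driven when A vanishes identically (within 1e-9 of the rate
scale), otherwise noise-regulation-dominated when the average absolute
regulated-noise term exceeds the average absolute deterministic term,
else deterministic-dominated.

## Identification

The fitting error is the scaled sum of absolute deviations between
simulated and target frequency distributions: Σ|sim − exp| / (2 Σ exp),
a strict [0, 1] bound for relative frequencies, with the simulation
rescaled to the experimental cell count first (the fit compares
shapes); multi-time-point errors are averaged. Feasibility thresholds
default to 0.05 for equilibrium fits and 0.07 for dynamic multi-
distribution fits.

NDO proposes componentwise normal perturbations of the lowest-error
reference found so far, clipped to [0, 1], with
σ(e) = σ_min + (σ_max − σ_min)·min(e/e₀, 1); the defaults
σ_min = 0.01, σ_max = 0.2, e₀ = 0.5 are this package's convention for
the exploration/exploitation trade-off (σ_max → 0 degenerates to no
movement, large fixed σ approaches random restart). Acceptance is
strict improvement only, so the best-so-far error is non-increasing
within a trajectory. Restarts initialise uniformly; every evaluated
point is recorded into a 16-bins-per-dimension grid (bin =
min(⌊16v⌋, 15)) that keeps the minimum error and parameters per cell —
the coverage monitor for search exhaustiveness. Local sensitivity uses
a symmetric central-difference Hessian of the objective, eigen-
decomposed and sorted by absolute eigenvalue.

## Synthetic data

**Labelling (2-D) generator.** The extended rate equation tracks
(n, l): total and labelled molecules per cell. During the pulse every
production event increments both n and l; degradation removes a
uniformly random molecule, so it decrements l with probability l/n;
division (when growth is on) partitions labelled and unlabelled pools
independently binomially. The bookkeeping guarantees l ≤ n and makes
the n-marginal exactly the 1-D dynamics (machine-precision consistency
is asserted in tests). The default design is a 6-minute pulse measured
at its end, from an unlabelled equilibrium population with growth off
(the labelling analyses are population-averaged per cell).

**Rate recovery (PAV).** From labelled/unlabelled totals L, U and the
pre-pulse total T0: λ̂ = −ln(U/T0)/Δ and α̂ = λ̂L/(1 − e^{−λ̂Δ}) (with
the λ → 0 limit α̂ = L/Δ), giving per-cell population-averaged
estimates P̄̂ = α̂/M and D̄̂ = λ̂·(T0/M). These are first-order exact
for general piecewise-linear degradation and exact for linear
degradation; at Δ = 6 min they recover the true population-averaged
rates of mass-contained random systems at N = 30 to well under 5 %
mean relative error.

**Single-cell tracking.** Exact continuous-time simulation by thinning:
candidate events arrive at the constant bound rate (the maximum of
P + D + G over all states, itself bounded by the caps), are accepted
with probability (P + D + G)/Λ and typed proportionally. Phase
advances are recorded as growth events and the phase-k growth event is
a division, after which one daughter (uniformly chosen) is followed so
the record stays a single timeline. Frame sampling reads the state at
multiples of Δ; reconstruction from frames turns successive differences
into pseudo-events (+c → c productions, −c → c degradations, attributed
to the earlier frame's state) — an approximation that degrades as Δ
grows because cancelling event pairs within a frame are invisible.

Per-state rate reconstruction divides event counts by occupancy time
(the maximum-likelihood estimate the exponential waiting-time histogram
yields) and splits the total rate by relative event frequencies.
Occupancy-weighted reconstruction error falls like 1/√(observation
time), and exact event times dominate frame-sampled data in
expectation when both are scored on their common support with common
weights.

**Fluorescence mapping and smoothing.** Intensity histograms map
affinely to molecule numbers with the minimum intensity at 0 and the
0.99 intensity quantile at ⌊2N/3⌋, keeping the mass in the lower two
thirds of the range; counts are aggregated per molecule bin with the
total preserved. Histogram smoothing fits a penalized regression
spline (GCV-chosen smoothing) to log(count + 1) — variance-stabilising
for counts — and renormalises the back-transformed estimate to the
original total.

**Random reference systems** draw P/D y-set points uniformly from
[0, 6] events/h and redraw until the stationary 99 % quantile lies in
the lower two thirds of [0, N], the same mass-placement convention as
the fluorescence mapping. This both avoids boundary artefacts and
guarantees the equilibrium sits at an interior attractor where P ≈ D,
so relative errors on both rates are well defined.

## Method comparison

All six error functionals score a candidate rate system against one
reference data set generated from the true parameters: scaled-L1 on the
1-D equilibrium histogram (Freq1D) and on the flattened (n, l) table
(Freq2D); absolute deviation of model-predicted population-averaged
rates from the labelling estimates (RatesPAV); occupancy-weighted mean
absolute deviation of the candidate's curves from the per-state
reconstructions (RatesSCTid from exact events, RatesSCT from 1-minute
frames); and the continuous-time negative log-likelihood of the event
data (LogLikeSCT). The rate-deviation norm and the cross-method
calibration are this package's conventions: min–max affine scaling onto
the Freq2D range (optionally anchored at zero), which preserves
candidate ordering. Distance profiles use Euclidean distance on the
0/1-scaled parameters, by default excluding PY3 and DY3 (the upper-
range set points are poorly identifiable and mostly add noise to the
distance axis), with centred windows of width 0.05 and the mean of the
lowest 1 % of errors per window. Parameter spreads are five-number
summaries of the sub-threshold (error ≤ 0.02) candidate set; on
references whose upper molecule range is scarcely populated, PY3 and
DY3 show by far the largest spread.

RatesPAV compresses a six-parameter system into two numbers, so
distinct systems can score identically; the test battery asserts its
optimum at the truth only up to this intrinsic degeneracy (a 0.05
events/h tolerance, the scale of the estimator's truncation bias).

## Trajectory analysis

Gene trajectories carry expression T and population-averaged rates P, D
on a 7-point grid at 6-minute spacing (0–36 min); expression is treated
as mean molecules per cell, so no cell-count normalisation is applied.
Smoothing uses generalised-cross-validated smoothing splines whose
derivatives define DA = dA/dt and DB = dB/dt; the sign of corr(DA, DB)
separates production-dominated (+) from degradation-dominated (−)
regulation when the rates share a common component. Pearson statistics
(corPD, corDADB, corPT, corDT) are reported as missing for constant
series. Permutation nulls enumerate all m! time orderings of the
second series of a pair (equivalent in distribution to permuting
either; beyond 9 points a sampling mode takes over); because the
correlation is bilinear in the centred series with permutation-
invariant norms, the null mean is exactly zero, and the observed value
sits at the identity permutation. Trends are signs of least-squares
slopes, with a zero slope classified "+" by documented convention.

Clustering standardises each expression trajectory (mean 0, population
sd 1 — the population-sd convention makes each time point of a
standardised random series have unit variance, which is what makes
"within-cluster sd ≈ 1 for random data" the correct null), then cuts a
complete-linkage tree on the correlation distance d = 1 − r at 0.15;
anti-correlated profiles are biologically distinct regulation, so
d = 1 − r rather than 1 − |r|. Within-cluster variation takes the sd
(ddof = 1) across member genes per time point first, then averages over
time; singleton clusters are excluded, and the sds are regressed
against the cluster-wise mean expression trend.

The synthetic yeast-like generator draws genes from four archetypes
(decreasing/increasing expression × degradation-/production-dominated,
default weights 0.37/0.29/0.22/0.12, i.e. 66 % decreasing expression)
sharing one logistic upregulation step centred between minutes 12 and
18; dominance is which rate takes the larger step amplitude, and the
baseline production–degradation offset is drawn large enough that
dT/dt keeps one sign, making the expression trend the archetype's by
construction. An independent smooth low-order component per rate
(scale 0.2 events/h by default) diversifies expression shapes into the
cluster granularity real time courses show; with it and observation
noise switched off the archetypes are pure (corPD = 1) and the sign
statistics recover them exactly. What the generator does not emulate:
microarray measurement error structure, quality filtering, absolute
expression scales, or any coupling between expression level and rate
noise — so passing tests show the pipeline's statistics behave
correctly on data with known structure, not that real yeast data would
yield the published fractions.

## Virtual treatments

A treatment multiplies the production or degradation curve's y-set
points (for degradation this is identical to scaling the per-molecule
coefficient λ(n) = D(n)/n, because of the (0, 0) anchor), either by an
explicit factor or calibrated by bisection so the post-treatment
zero-growth equilibrium hits a target mean. Runs equilibrate the
ground state, integrate the treated system over a 7.5-h horizon
(essentially re-equilibrated for the systems considered, so reverse
treatments restore the ground state within 1 %), and report
before/after means and standard deviations; proliferation is off by
default.

The birth–death reference (α = 6/h, λ = 1/h, N = 60, caps disabled)
has the truncated-Poisson ground state (mean 6.0, sd 2.4); the
production dose calibrated to mean 10.6 is ×1.77 (+77 % mean shift)
and widens the distribution to sd 3.3. The contrasting crowding
scenario keeps degradation constant at 6/h for n ≥ 1 (λ(n) = 6/n) and
down-regulates production with n. Its default profile — set points
(2, 12), (7, 4), (11, 1.5), uncapped — is chosen so that production
falls steeply through the degradation level at the attractor (ground
mean 6.0, comparable to the reference) and then flattens: a
multiplicatively scaled profile re-crosses the degradation level on
the shallow tail at a similar slope, so the local fluctuation balance
B/(2|A′|) at the attractor, and hence the distribution width, is
nearly treatment-invariant (|Δsd| ≈ 0.0 versus +0.8 for the
birth–death case under identical doses), while the mean response is
roughly halved. The steep-then-shallow shape is the defining feature
of this regulation class; a production profile decaying gently to zero
over the whole range would instead broaden strongly under treatment.

## Problem sizes and defaults

Molecule ranges N = 15–60 (the regime of low-copy signalling proteins,
where stochasticity matters and integration is cheap), k = 5 phases,
dt = 1 min. NDO budgets: 200 iterations per trajectory for equilibrium
fits, 400 for dynamic fits. Tracking references use tens of cells for
tens of hours (thousands of events); labelling uses deterministic 2-D
integration, so its only error is the Euler step. The test suite's
simulation sizes (20 random systems for estimator validation, 100
seeded optimiser runs, 600-gene clustering) were chosen as the smallest
sizes at which the sampling error of each check is comfortably below
its assertion tolerance.

## Known limitations

* The Euler-forward scheme is first-order; equilibria are exact (fixed
  points are step-size independent) but transient trajectories carry
  O(dt) error.
* The frame-based reconstruction's pseudo-event rule cannot see
  cancelling event pairs within a frame; its bias grows with the frame
  interval and the local total rate.
* The feasible-region grid stores only the per-cell minimum; it
  monitors coverage, not the full error landscape.
* Fitting real cytometry data requires the user to bin, smooth and map
  intensities to molecule numbers first (tools provided); raw
  instrument files are out of scope.
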