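"""Multi-phase cell-cycle rate equation, summaries and noise decomposition.

The central object is a frequency table F(n, i): the mean number of cells
holding n = 0..N molecules in cell-cycle phase i = 1..k.  Its balance
equation couples molecule production (n -> n+1), degradation (n -> n-1),
progression through the k phases at the growth rate, and division of
phase-k cells into two phase-1 daughters with binomial molecule
partitioning.  All rates are evaluated at the dilution-corrected
concentration floor(n / v_i), with cell volume v_i growing linearly from
1 to 2 across the cycle.

For zero growth the equation reduces to a one-dimensional chemical master
equation for a birth-death chain, whose stationary distribution has the
classical detailed-balance closed form — exposed here as
:func:`stationary_distribution` and used as an independent oracle for the
Euler integrator.

The Fokker-Planck view splits the local dynamics of the marginal density
p(x) into a deterministic drift term built on A(x) = P(x) - D(x), a
regulated-noise term built on gradients of B(x) = P(x) + D(x), and a
diffusion term.  Population averages of |A_FP| and |DB_FP| classify the
regime: noise-driven (A = 0 as a function), noise regulation-dominated
(|DB_FP| average exceeds |A_FP| average), or deterministic-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rates import InductionSchedule, RateSystem, ValidationError

DEFAULT_DT = 1.0 / 60.0  # hours (1 minute Euler step)


class StepSizeError(RuntimeError):
    """An Euler step produced negative frequencies; dt is too large."""


@dataclass
class CellCycleConfig:
    """Integration configuration.

    k is the phase count (5 throughout, following the multi-phase cell
    cycle model); dt the Euler-forward step in hours; partition_mode
    selects how molecules are split among daughters at division.
    """

    k: int = 5
    dt: float = DEFAULT_DT
    partition_mode: str = "binomial"  # or "halving"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("phase count k must be >= 2")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.partition_mode not in ("binomial", "halving"):
            raise ValidationError("partition_mode must be 'binomial' or 'halving'")


@dataclass
class PopulationState:
    """Frequency table F(n, i) (cells per state) at time t (hours)."""

    F: np.ndarray  # shape (N+1, k)
    t: float = 0.0

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValidationError("F must be 2D (molecule number x phase)")
        if not np.all(np.isfinite(self.F)) or np.any(self.F < 0):
            raise ValidationError("frequencies must be finite and >= 0")
        if self.F.sum() <= 0:
            raise ValidationError("total cell count must be positive")

    @property
    def N(self) -> int:
        return self.F.shape[0] - 1

    @property
    def k(self) -> int:
        return self.F.shape[1]

    @property
    def M(self) -> float:
        """Total number of cells."""
        return float(self.F.sum())

    def copy(self) -> "PopulationState":
        return PopulationState(self.F.copy(), self.t)


def initial_state(N: int, k: int = 5, histogram=None, phase: int = 1) -> PopulationState:
    """All mass at n = 0 in phase 1, or spread per a supplied histogram."""
    F = np.zeros((N + 1, k))
    if histogram is None:
        F[0, phase - 1] = 1.0
    else:
        h = np.asarray(histogram, dtype=float)
        F[: h.size, phase - 1] = h
    return PopulationState(F, 0.0)


def partition_matrix(N: int, mode: str = "binomial") -> np.ndarray:
    """Division kernel B[n, m] = prob(daughter gets n | mother had m).

    Binomial: b(n | m, 1/2).  Halving: odd m split as floor/ceil with
    equal weight.  Columns sum to one; the expected daughter load is m/2,
    so molecules are conserved in expectation across the two daughters.
    """
    m = np.arange(N + 1)
    if mode == "binomial":
        B = stats.binom.pmf(m[:, None], m[None, :], 0.5)
    elif mode == "halving":
        B = np.zeros((N + 1, N + 1))
        lo, hi = m // 2, (m + 1) // 2
        B[lo, m] += 0.5
        B[hi, m] += 0.5
    else:
        raise ValidationError(f"unknown partition mode {mode!r}")
    return B


class _Stepper:
    """Precomputed tables for repeated Euler steps of one rate system."""

    def __init__(self, rates: RateSystem, cfg: CellCycleConfig):
        self.cfg = cfg
        self.N = rates.N
        tables = rates.rate_tables(cfg.k)
        self.P, self.D, self.G = tables["P"], tables["D"], tables["G"]
        # boundary handling: no mass leaves [0, N]
        self.P = self.P.copy()
        self.P[self.N, :] = 0.0  # production outflow from n = N suppressed
        self.D = self.D.copy()
        self.D[0, :] = 0.0       # D(0) = 0 anchor; enforced defensively
        self.B = partition_matrix(self.N, cfg.partition_mode)

    def step(self, F: np.ndarray, dt: float) -> np.ndarray:
        outP = self.P * F * dt
        outD = self.D * F * dt
        outG = self.G * F * dt
        Fn = F - outP - outD - outG
        neg = Fn[Fn < 0]
        if neg.size:
            # tolerate roundoff-scale negativity in essentially empty
            # states (uncapped rates can exceed 1/dt where occupancy is
            # ~1e-30); material mass loss signals a genuine step-size
            # problem
            if -neg.sum() > 1e-12 * F.sum():
                raise StepSizeError(
                    "per-state outflow exceeds occupancy; reduce dt "
                    f"(dt = {dt:g} h)"
                )
            Fn = np.clip(Fn, 0.0, None)
        Fn[1:, :] += outP[:-1, :]
        Fn[:-1, :] += outD[1:, :]
        if self.cfg.k > 1:
            Fn[:, 1:] += outG[:, :-1]           # phase progression
        Fn[:, 0] += 2.0 * (self.B @ outG[:, -1])  # division into phase 1
        return Fn


def step(state: PopulationState, rates: RateSystem, cfg: CellCycleConfig,
         dt: float | None = None) -> PopulationState:
    """One Euler-forward update of the population rate equation."""
    dt = cfg.dt if dt is None else dt
    stepper = _Stepper(rates, cfg)
    return PopulationState(stepper.step(state.F, dt), state.t + dt)


def integrate(state: PopulationState,
              rates: RateSystem | InductionSchedule,
              cfg: CellCycleConfig,
              t_end: float,
              record_times=None) -> list[PopulationState]:
    """Euler-forward integration up to ``t_end`` hours.

    With an :class:`InductionSchedule` the production/degradation tables
    are re-blended at every step according to I(t).  Snapshots are
    recorded at the requested times (nearest step; always includes the
    final state when ``record_times`` is None).
    """
    if t_end < state.t:
        raise ValidationError("t_end must be >= state.t")
    schedule = rates if isinstance(rates, InductionSchedule) else None
    if schedule is not None:
        sf = _Stepper(schedule.fast, cfg)
        ss = _Stepper(schedule.slow, cfg)
        stepper = _Stepper(schedule.fast, cfg)  # reused container
    else:
        stepper = _Stepper(rates, cfg)

    n_steps = int(round((t_end - state.t) / cfg.dt))
    times = state.t + cfg.dt * np.arange(n_steps + 1)
    if record_times is None:
        record_idx = {n_steps}
    else:
        record_idx = {int(np.argmin(np.abs(times - tr))) for tr in record_times}

    F = state.F.copy()
    out: list[PopulationState] = []
    if 0 in record_idx:
        out.append(PopulationState(F.copy(), float(times[0])))
    for j in range(n_steps):
        if schedule is not None:
            # I(t) blends production and degradation; growth switches
            # instantly to the activated system's profile at t = 0
            # (medium change acts on proliferation immediately)
            w = schedule.weight(float(times[j]))
            stepper.P = (1 - w) * sf.P + w * ss.P
            stepper.D = (1 - w) * sf.D + w * ss.D
            stepper.G = ss.G
        F = stepper.step(F, cfg.dt)
        if j + 1 in record_idx:
            out.append(PopulationState(F.copy(), float(times[j + 1])))
    return out


def equilibrate(rates: RateSystem, cfg: CellCycleConfig,
                init: PopulationState | None = None,
                tol: float = 1e-10, max_hours: float = 72.0) -> PopulationState:
    """Integrate until the max-norm change per step drops below ``tol``.

    Frequencies are renormalised to unit cell count each step so the
    criterion measures distributional change even in growing populations.
    The 72 h default horizon corresponds to 3 days of cell culture.
    """
    state = initial_state(rates.N, cfg.k) if init is None else init.copy()
    stepper = _Stepper(rates, cfg)
    F = state.F / state.F.sum()
    t = state.t
    n_steps = int(round(max_hours / cfg.dt))
    for _ in range(n_steps):
        Fn = stepper.step(F, cfg.dt)
        Fn = Fn / Fn.sum()
        t += cfg.dt
        if np.max(np.abs(Fn - F)) < tol:
            F = Fn
            break
        F = Fn
    return PopulationState(F, t)


def marginalise(state: PopulationState) -> np.ndarray:
    """Marginal frequency vector F(n) = sum_i F(n, i)."""
    return state.F.sum(axis=1)


def stationary_distribution(rates: RateSystem) -> np.ndarray:
    """Detailed-balance stationary law of the zero-growth birth-death chain.

    pi(n) proportional to prod_{j=1..n} P(j-1) / D(j), normalised.
    Valid whenever G = 0 (the rate equation is then a 1D CME with
    nearest-neighbour jumps, so detailed balance holds exactly).  Raises
    if an interior state with inflow has zero degradation (absorbing
    structure: no stationary law on the full range).
    """
    if rates.has_growth():
        raise ValidationError("stationary closed form requires zero growth")
    N = rates.N
    n = np.arange(N + 1, dtype=float)
    P = rates.P(n)
    P[N] = 0.0  # reflecting boundary, matching the integrator
    D = rates.D(n)
    logpi = np.full(N + 1, -np.inf)
    logpi[0] = 0.0
    acc = 0.0
    for j in range(1, N + 1):
        if P[j - 1] <= 0:
            break  # chain truncated: states above j - 1 unreachable
        if D[j] <= 0:
            raise ValidationError(
                f"D({j}) = 0 with P({j - 1}) > 0: absorbing structure, "
                "closed-form stationary law inapplicable"
            )
        acc += np.log(P[j - 1]) - np.log(D[j])
        logpi[j] = acc
    pi = np.exp(logpi - np.max(logpi[np.isfinite(logpi)]))
    return pi / pi.sum()


def distribution_moments(freq: np.ndarray) -> tuple[float, float]:
    """Mean and standard deviation of a frequency vector over n = 0..len-1."""
    freq = np.asarray(freq, dtype=float)
    p = freq / freq.sum()
    n = np.arange(freq.size)
    mean = float(p @ n)
    var = float(p @ (n - mean) ** 2)
    return mean, np.sqrt(var)


# ---------------------------------------------------------------------
# population summaries (molecule-balance quantities)
# ---------------------------------------------------------------------

@dataclass
class PopulationSummary:
    Pbar: float
    Dbar: float
    dPbar: float
    dDbar: float
    Abar: float
    corr_w: float
    M: float
    T: float
    dynamics: str | None = None


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def summarise(state: PopulationState, rates: RateSystem,
              classify: bool = True) -> PopulationSummary:
    """Population-averaged rates, slopes, weighted P-D correlation.

    Averages weight the dilution-corrected rates P(n, i), D(n, i) by the
    occupation probabilities p(n, i) = F(n, i) / M.  The P-D correlation
    is computed per cell-cycle phase with weights p(n, i), then averaged
    across phases weighted by phase occupancy.  Abar = Pbar - Dbar drives
    the total molecule count: dT/dt = M * Abar for the regulation part of
    the dynamics (growth/division terms are characterised separately).
    """
    if state.M <= 0:
        raise ValidationError("empty population")
    k = state.k
    tables = rates.rate_tables(k)
    P, D = tables["P"], tables["D"]
    p = state.F / state.M
    Pbar = float((p * P).sum())
    Dbar = float((p * D).sum())
    dP = np.gradient(P, axis=0)
    dD = np.gradient(D, axis=0)
    dPbar = float((p * dP).sum())
    dDbar = float((p * dD).sum())
    n = np.arange(state.N + 1, dtype=float)
    T = float(n @ marginalise(state))

    # phase-wise weighted correlation, averaged across phases
    corrs, phase_w = [], []
    for i in range(k):
        wi = p[:, i]
        tot = wi.sum()
        if tot <= 0:
            continue
        c = _weighted_corr(P[:, i], D[:, i], wi)
        if np.isfinite(c):
            corrs.append(c)
            phase_w.append(tot)
    corr_w = float(np.average(corrs, weights=phase_w)) if corrs else np.nan

    dyn = None
    if classify and state.N >= 3:
        dyn = classify_dynamics(fp_decompose(state, rates), rates)
    return PopulationSummary(Pbar, Dbar, dPbar, dDbar, Pbar - Dbar, corr_w,
                             state.M, T, dyn)


# ---------------------------------------------------------------------
# Fokker-Planck decomposition (diagnostic, not integrated forward)
# ---------------------------------------------------------------------

@dataclass
class FPDecomposition:
    deterministic: np.ndarray   # d/dx(-A p)
    regulated_noise: np.ndarray  # d/dx(B' p) - 1/2 B'' p
    diffusion: np.ndarray       # (B/2) p''
    abs_A_mean: float           # sum_x p(x) |deterministic(x)| (interior)
    abs_DB_mean: float
    abs_diff_mean: float


def _central_d1(f: np.ndarray) -> np.ndarray:
    out = np.full_like(f, np.nan)
    out[1:-1] = (f[2:] - f[:-2]) / 2.0
    return out


def _central_d2(f: np.ndarray) -> np.ndarray:
    out = np.full_like(f, np.nan)
    out[1:-1] = f[2:] - 2.0 * f[1:-1] + f[:-2]
    return out


def fp_decompose(state: PopulationState, rates: RateSystem) -> FPDecomposition:
    """Fokker-Planck term split of the marginal density p(x).

    All derivatives are central finite differences on the unit molecule
    grid; boundary entries (where a centred stencil does not fit) are NaN
    and excluded from the probability-weighted absolute averages.  The
    rate curves enter through A = P - D and B = P + D evaluated directly
    on x (the decomposition characterises the regulation, not the
    cell-cycle machinery).
    """
    N = state.N
    if N < 3:
        raise ValidationError("molecule range too small for FP differences")
    x = np.arange(N + 1, dtype=float)
    p = marginalise(state)
    p = p / p.sum()
    A = rates.P(x) - rates.D(x)
    B = rates.P(x) + rates.D(x)

    det = _central_d1(-A * p)
    reg = _central_d1(_central_d1(B) * p) - 0.5 * _central_d2(B) * p
    diff = 0.5 * B * _central_d2(p)

    def _avg(term):
        m = np.isfinite(term)
        return float(np.sum(p[m] * np.abs(term[m])))

    return FPDecomposition(det, reg, diff, _avg(det), _avg(reg), _avg(diff))


NOISE_DRIVEN = "noise_driven"
NOISE_REGULATION_DOMINATED = "noise_regulation_dominated"
DETERMINISTIC_DOMINATED = "deterministic_dominated"


def classify_dynamics(fp: FPDecomposition, rates: RateSystem,
                      atol: float = 1e-9) -> str:
    """Label the dynamical regime from the FP averages.

    Noise-driven dynamics means P(x) = D(x) as functions (the
    deterministic component vanishes identically); otherwise the regime
    is decided by comparing the average absolute regulated-noise and
    deterministic FP terms.
    """
    x = np.arange(rates.N + 1, dtype=float)
    A = rates.P(x) - rates.D(x)
    scale = max(np.max(rates.P(x) + rates.D(x)), 1.0)
    if np.max(np.abs(A)) <= atol * scale:
        return NOISE_DRIVEN
    if fp.abs_DB_mean > fp.abs_A_mean:
        return NOISE_REGULATION_DOMINATED
    return DETERMINISTIC_DOMINATED
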