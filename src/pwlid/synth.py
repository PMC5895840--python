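"""Synthetic data generators: histograms, metabolic labelling, tracking.

Three semi-empirical data types are produced from a known rate system:

* 1D frequency histograms of molecule numbers over time (what flow
  cytometry delivers after fluorescence-to-molecule mapping);
* 2D labelled/total distributions from an extended rate equation that
  tracks, per cell, the total number n of molecules and the number l
  that were synthesised after a labelling pulse began (4sU metabolic
  labelling: the analogue enters nascent transcripts only, and random
  degradation removes a labelled molecule with probability l/n);
* single-cell tracking (SCT) event trajectories simulated exactly in
  continuous time by thinning (rejection sampling against the global
  rate caps), optionally degraded to frame-based observations.

Also here: the affine fluorescence-to-molecule mapping and the
histogram smoothing used to pre-process noisy intensity histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .population import (CellCycleConfig, PopulationState, equilibrate,
                         initial_state, integrate, marginalise,
                         partition_matrix, stationary_distribution)
from .rates import InductionSchedule, RateSystem, ValidationError, pwl_system


# ---------------------------------------------------------------------
# 1D histograms
# ---------------------------------------------------------------------

def simulate_freq1d(rates, cfg: CellCycleConfig, times,
                    init: PopulationState | None = None) -> dict[float, np.ndarray]:
    """Marginal frequency histograms F(n) at the requested times.

    ``rates`` may be a :class:`RateSystem` or an
    :class:`InductionSchedule`.  Default initial condition: all mass at
    n = 0 in phase 1.
    """
    N = rates.N
    state = initial_state(N, cfg.k) if init is None else init
    times = sorted(float(t) for t in times)
    states = integrate(state, rates, cfg, max(times), record_times=times)
    return {s.t: marginalise(s) for s in states}


def equilibrium_histogram(rates: RateSystem, cfg: CellCycleConfig | None = None,
                          exact: bool = True) -> np.ndarray:
    """Stationary marginal distribution (closed form for zero growth)."""
    if exact and not rates.has_growth():
        return stationary_distribution(rates)
    cfg = cfg or CellCycleConfig()
    return marginalise(equilibrate(rates, cfg))


# ---------------------------------------------------------------------
# metabolic labelling (extended 2D rate equation)
# ---------------------------------------------------------------------

@dataclass
class LabellingDesign:
    """Labelling interval (h), measurement time points (h), growth flag."""

    interval: float = 0.1       # 6-minute pulse
    times: tuple = (0.1,)
    growth: bool = False

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValidationError("labelling interval must be positive")
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0) and t.size > 1:
            raise ValidationError("measurement times must be increasing")


@dataclass
class Labelled2DDistribution:
    """Joint frequencies over (total n, labelled l <= n) per phase."""

    F2: np.ndarray  # shape (N+1, N+1, k); entry [n, l, i]
    t: float

    def __post_init__(self) -> None:
        N = self.F2.shape[0] - 1
        n_idx, l_idx = np.meshgrid(np.arange(N + 1), np.arange(N + 1), indexing="ij")
        if np.any(self.F2[l_idx > n_idx] > 1e-12):
            raise ValidationError("mass at l > n: inconsistent labelling table")

    @property
    def N(self) -> int:
        return self.F2.shape[0] - 1

    def marginal_n(self) -> np.ndarray:
        return self.F2.sum(axis=(1, 2))

    def marginal_l(self) -> np.ndarray:
        return self.F2.sum(axis=(0, 2))

    def table(self) -> np.ndarray:
        """Phase-marginalised (n, l) table."""
        return self.F2.sum(axis=2)

    def totals(self) -> tuple[float, float, float]:
        """(labelled total L, unlabelled total U, cell count M)."""
        N = self.N
        tab = self.table()
        l_grid = np.arange(N + 1)[None, :]
        n_grid = np.arange(N + 1)[:, None]
        L = float((tab * l_grid).sum())
        U = float((tab * (n_grid - l_grid)).sum())
        return L, U, float(tab.sum())


class _Stepper2D:
    """Euler tables for the extended (n, l) rate equation."""

    def __init__(self, rates: RateSystem, cfg: CellCycleConfig):
        self.cfg = cfg
        self.N = N = rates.N
        tables = rates.rate_tables(cfg.k)
        self.P = tables["P"].copy()
        self.P[N, :] = 0.0
        self.D = tables["D"].copy()
        self.D[0, :] = 0.0
        self.G = tables["G"]
        # probability that a uniformly chosen molecule is labelled
        n_grid = np.arange(N + 1, dtype=float)[:, None]
        l_grid = np.arange(N + 1, dtype=float)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(n_grid > 0, l_grid / n_grid, 0.0)
        self.frac = np.clip(frac, 0.0, 1.0)
        self.B = partition_matrix(N, cfg.partition_mode)

    def step(self, F2: np.ndarray, dt: float, labelling: bool) -> np.ndarray:
        N, k = self.N, self.cfg.k
        P = self.P[:, None, :]
        D = self.D[:, None, :]
        G = self.G[:, None, :]
        frac = self.frac[:, :, None]
        outP = P * F2 * dt
        outD = D * F2 * dt
        outG = G * F2 * dt
        Fn = F2 - outP - outD - outG
        neg = Fn[Fn < 0]
        if neg.size and -neg.sum() > 1e-12 * F2.sum():
            raise ValidationError("2D Euler step too large; reduce dt")
        Fn = np.clip(Fn, 0.0, None)
        if labelling:  # production increments n and l
            Fn[1:, 1:, :] += outP[:-1, :-1, :]
        else:
            Fn[1:, :, :] += outP[:-1, :, :]
        # degradation removes a random molecule: labelled w.p. l/n
        outD_lab = outD * frac
        outD_unl = outD * (1.0 - frac)
        Fn[:-1, :-1, :] += outD_lab[1:, 1:, :]
        Fn[:-1, :, :] += outD_unl[1:, :, :]
        if k > 1:
            Fn[:, :, 1:] += outG[:, :, :-1]
        # division: labelled and unlabelled pools partition independently
        div = outG[:, :, -1]
        if div.any():
            # U[l, u] = mass of phase-k dividing mothers with l labelled,
            # u unlabelled molecules
            U = np.zeros((N + 1, N + 1))
            n_idx, l_idx = np.nonzero(div)
            U[l_idx, n_idx - l_idx] = div[n_idx, l_idx]
            D2 = self.B @ U @ self.B.T  # daughters: [l', u']
            lp, up = np.nonzero(D2)
            np.add.at(Fn[:, :, 0], (lp + up, lp), 2.0 * D2[lp, up])
        return Fn


def simulate_labelling(rates: RateSystem, design: LabellingDesign,
                       cfg: CellCycleConfig | None = None,
                       init: np.ndarray | None = None) -> list[Labelled2DDistribution]:
    """Integrate the extended rate equation through a labelling pulse.

    The population starts fully unlabelled (l = 0), by default at the
    equilibrium of the 1D system; labelling is active on [0, interval].
    Returns the 2D distributions at the design's measurement times.
    """
    cfg = cfg or CellCycleConfig()
    if not design.growth and rates.has_growth():
        raise ValidationError("design has growth off but the rate system grows")
    N = rates.N
    if init is None:
        init = equilibrium_histogram(rates, cfg)
    init = np.asarray(init, dtype=float)
    F2 = np.zeros((N + 1, N + 1, cfg.k))
    F2[: init.size, 0, 0] = init
    stepper = _Stepper2D(rates, cfg)

    times = sorted(float(t) for t in design.times)
    t_end = max(times)
    n_steps = int(round(t_end / cfg.dt))
    grid = cfg.dt * np.arange(n_steps + 1)
    record_idx = {int(np.argmin(np.abs(grid - tr))): tr for tr in times}
    out = []
    if 0 in record_idx:
        out.append(Labelled2DDistribution(F2.copy(), 0.0))
    for j in range(n_steps):
        labelling = grid[j] < design.interval - 1e-12
        F2 = stepper.step(F2, cfg.dt, labelling)
        if j + 1 in record_idx:
            out.append(Labelled2DDistribution(F2.copy(), float(grid[j + 1])))
    return out


# ---------------------------------------------------------------------
# single-cell tracking (exact continuous-time simulation via thinning)
# ---------------------------------------------------------------------

class Event(NamedTuple):
    time: float
    type: str     # production | degradation | growth | division
    n_before: int
    n_after: int
    phase: int    # phase in which the event occurred


@dataclass
class SCTTrajectory:
    """Timed event list for one tracked cell lineage.

    At division one daughter is followed (chosen uniformly), so the
    record remains a single timeline; ``growth`` events are cell-cycle
    phase advances, ``division`` the phase-k growth event.
    """

    cell: int
    n0: int
    t_end: float
    events: list = field(default_factory=list)
    t_start: float = 0.0
    frame_interval: float | None = None

    def state_at(self, t: float) -> int:
        n = self.n0
        for ev in self.events:
            if ev.time > t:
                break
            n = ev.n_after
        return n

    def occupancy(self, N: int, k: int = 1) -> np.ndarray:
        """Time spent in each (n, phase) state, shape (N+1, k)."""
        occ = np.zeros((N + 1, k))
        t, n, ph = self.t_start, self.n0, 1
        for ev in self.events:
            occ[n, ph - 1] += ev.time - t
            t = ev.time
            n = ev.n_after
            ph = ev.phase + 1 if ev.type == "growth" else (1 if ev.type == "division" else ev.phase)
        occ[n, ph - 1] += self.t_end - t
        return occ

    def event_counts(self, N: int, types=("production", "degradation"),
                     k: int = 1) -> dict[str, np.ndarray]:
        counts = {tp: np.zeros((N + 1, k)) for tp in types}
        for ev in self.events:
            if ev.type in counts:
                counts[ev.type][ev.n_before, ev.phase - 1] += 1
        return counts


def simulate_sct(rates: RateSystem, cfg: CellCycleConfig, n_cells: int,
                 duration: float, rng: np.random.Generator,
                 init="stationary") -> list[SCTTrajectory]:
    """Exact event trajectories by thinning against the global rate bound.

    Candidate events arrive at the constant bound rate Lambda >= P + D + G
    everywhere; each candidate is accepted with probability
    (P + D + G) / Lambda at the current state and typed proportionally to
    the three rates.  Division partitions the molecules (binomially or by
    halving, per the config) and the tracker follows one daughter.
    """
    if duration <= 0:
        raise ValidationError("duration must be positive")
    N, k = rates.N, cfg.k
    tables = rates.rate_tables(k)
    P = tables["P"].copy()
    P[N, :] = 0.0
    D = tables["D"].copy()
    D[0, :] = 0.0
    G = tables["G"]
    lam = float((P + D + G).max())
    if lam <= 0:
        return [SCTTrajectory(c, _draw_init(rates, init, rng), duration)
                for c in range(n_cells)]

    trajs = []
    for c in range(n_cells):
        n = n_init = _draw_init(rates, init, rng)
        ph = 1
        t = 0.0
        events: list[Event] = []
        while True:
            t += rng.exponential(1.0 / lam)
            if t >= duration:
                break
            p, d, g = P[n, ph - 1], D[n, ph - 1], G[n, ph - 1]
            u = rng.uniform(0.0, lam)
            if u < p:
                events.append(Event(t, "production", n, n + 1, ph))
                n += 1
            elif u < p + d:
                events.append(Event(t, "degradation", n, n - 1, ph))
                n -= 1
            elif u < p + d + g:
                if ph < k:
                    events.append(Event(t, "growth", n, n, ph))
                    ph += 1
                else:
                    if cfg.partition_mode == "binomial":
                        n_new = int(rng.binomial(n, 0.5))
                    else:
                        n_new = int(n // 2 if rng.uniform() < 0.5 else (n + 1) // 2)
                    events.append(Event(t, "division", n, n_new, ph))
                    n = n_new
                    ph = 1
            # else: thinned candidate, no event
        trajs.append(SCTTrajectory(c, n_init, duration, events))
    return trajs


def _draw_init(rates: RateSystem, init, rng: np.random.Generator) -> int:
    if isinstance(init, (int, np.integer)):
        return int(init)
    if init == "stationary":
        if rates.has_growth():
            raise ValidationError("stationary init requires zero growth; pass an int")
        pi = stationary_distribution(rates)
        return int(rng.choice(pi.size, p=pi))
    pi = np.asarray(init, dtype=float)
    pi = pi / pi.sum()
    return int(rng.choice(pi.size, p=pi))


def frames_from_trajectory(traj: SCTTrajectory, delta: float) -> np.ndarray:
    """Frame-sampled molecule numbers at times 0, delta, 2*delta, ...

    Events between frames are unobserved — the realistic degradation of
    ideal tracking to time-lapse imaging.
    """
    if delta <= 0:
        raise ValidationError("frame interval must be positive")
    times = np.arange(0.0, traj.t_end + 1e-12, delta)
    frames = np.empty(times.size, dtype=int)
    n = traj.n0
    ei = 0
    evs = traj.events
    for j, t in enumerate(times):
        while ei < len(evs) and evs[ei].time <= t:
            n = evs[ei].n_after
            ei += 1
        frames[j] = n
    return frames


# ---------------------------------------------------------------------
# fluorescence mapping and histogram smoothing
# ---------------------------------------------------------------------

@dataclass
class FluorescenceMap:
    """Affine intensity -> molecule-number map, clipped to [0, N]."""

    a: float
    b: float
    N: int

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValidationError("fluorescence scale a must be positive")

    def __call__(self, intensity):
        m = np.rint(self.a * np.asarray(intensity, dtype=float) + self.b)
        return np.clip(m, 0, self.N).astype(int)


def map_fluorescence(intensities, counts, N: int,
                     quantile: float = 0.99) -> tuple[np.ndarray, FluorescenceMap]:
    """Map an intensity histogram to molecule numbers on [0, N].

    The affine map sends the minimum observed intensity to 0 and the
    ``quantile`` intensity to floor(2N/3), placing the distributional
    mass in the lower two thirds of the molecular range to keep it clear
    of the reflecting upper boundary.  Counts are aggregated per
    molecule bin; the total count is preserved.
    """
    x = np.asarray(intensities, dtype=float)
    c = np.asarray(counts, dtype=float)
    if x.size != c.size or x.size == 0 or c.sum() <= 0:
        raise ValidationError("need a non-empty intensity histogram")
    occupied = x[c > 0]
    if occupied.size < 2:
        raise ValidationError("degenerate (single-bin) histogram")
    order = np.argsort(x)
    x, c = x[order], c[order]
    cum = np.cumsum(c) / c.sum()
    xq = x[np.searchsorted(cum, quantile)] if quantile < 1 else x[-1]
    xmin = x[c > 0][0]
    if xq <= xmin:
        raise ValidationError("degenerate intensity range")
    target = int(2 * N // 3)
    a = target / (xq - xmin)
    fmap = FluorescenceMap(a, -a * xmin, N)
    hist = np.bincount(fmap(x), weights=c, minlength=N + 1)
    return hist, fmap


def smooth_histogram(counts, lam: float | None = None) -> np.ndarray:
    """Smooth a noisy histogram, preserving the total count.

    A penalized regression spline is fitted to log(count + 1) (variance-
    stabilising for counts) with GCV-chosen smoothing unless ``lam`` is
    given; the back-transformed estimate is clipped at zero and
    renormalised to the input total.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValidationError("counts must be >= 0")
    if c.size < 4 or c.sum() == 0:
        return c.copy()
    x = np.arange(c.size, dtype=float)
    spl = make_smoothing_spline(x, np.log1p(c), lam=lam)
    sm = np.clip(np.expm1(spl(x)), 0.0, None)
    if sm.sum() <= 0:
        return c.copy()
    return sm * (c.sum() / sm.sum())


# ---------------------------------------------------------------------
# seeded random reference systems
# ---------------------------------------------------------------------

def random_rate_system(N: int, rng: np.random.Generator, y_max: float = 6.0,
                       contain_mass: bool = True, max_tries: int = 200) -> RateSystem:
    """Random piecewise-linear P/D system with zero growth.

    y-set points are uniform in [0, y_max]; degradation keeps its (0, 0)
    anchor.  With ``contain_mass`` the draw is repeated until the
    stationary 99% quantile lies in the lower two thirds of [0, N] — the
    same mass-placement convention as the fluorescence mapping, keeping
    equilibria clear of the reflecting boundary.
    """
    for _ in range(max_tries):
        p_y = rng.uniform(0.0, y_max, 3)
        d_y = rng.uniform(0.0, y_max, 3)
        try:
            rs = pwl_system(N, p_y, d_y)
            if not contain_mass:
                return rs
            pi = stationary_distribution(rs)
            q99 = np.searchsorted(np.cumsum(pi), 0.99)
            if q99 <= 2 * N / 3:
                return rs
        except ValidationError:
            continue
    raise ValidationError("could not draw a mass-contained random system")
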