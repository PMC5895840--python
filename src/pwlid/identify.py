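"""Histogram error, noise-driven optimisation and feasible-region mapping.

The identification task: find 0/1-scaled y-set-point vectors whose
simulated frequency distributions deviate from target histograms by no
more than a fixed scaled-L1 error.  Because the data rarely pin the
parameters down to a point, the object of interest is the whole feasible
region, mapped by many random-restart optimisation trajectories and
recorded on a coarse grid of the unit hypercube.

NDO (noise-driven optimisation) proposes normal perturbations of the
best parameter vector encountered so far, with a perturbation scale that
shrinks as the reference error falls — wide scouting while the fit is
poor, fine adjustment near good fits.  Acceptance is strict improvement
only, so the reference is always the lowest-error point seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .rates import ValidationError

GRID_BINS = 16


def histogram_error(sim, exp, weights=None) -> float:
    """Scaled sum of absolute deviations between frequency distributions.

    ``sim`` and ``exp`` are frequency vectors, or lists of vectors for
    several time points.  Each simulated vector is first rescaled to the
    experimental total (the fit compares shapes at the experimental cell
    count); the per-time error is sum |sim - exp| / (2 * sum exp), a
    strict [0, 1] bound for relative frequencies; multi-time errors are
    averaged (equal weights unless given).
    """
    if isinstance(sim, np.ndarray) and sim.ndim == 1:
        sim, exp = [sim], [exp]
    elif not isinstance(sim, (list, tuple)):
        sim, exp = [np.asarray(sim)], [np.asarray(exp)]
    if len(sim) != len(exp):
        raise ValidationError("sim and exp must have the same number of time points")
    errs = []
    for s, e in zip(sim, exp):
        s = np.asarray(s, dtype=float)
        e = np.asarray(e, dtype=float)
        if s.shape != e.shape:
            raise ValidationError("sim and exp supports differ")
        tot = e.sum()
        if tot <= 0:
            raise ValidationError("experimental histogram is empty")
        s_tot = s.sum()
        if s_tot > 0:
            s = s * (tot / s_tot)
        errs.append(np.abs(s - e).sum() / (2.0 * tot))
    return float(np.average(errs, weights=weights))


@dataclass
class ErrorConfig:
    """Target histograms, per-time weights and the feasibility threshold."""

    targets: list
    times: list | None = None
    weights: list | None = None
    threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValidationError("feasibility threshold must be in (0, 1]")


@dataclass
class NDOConfig:
    iterations: int = 200       # per trajectory (400 for dynamic fits)
    sigma_min: float = 0.01     # perturbation scale in scaled units
    sigma_max: float = 0.2
    e0: float = 0.5             # error at which sigma saturates at sigma_max
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.sigma_min <= self.sigma_max:
            raise ValidationError("need 0 < sigma_min <= sigma_max")
        if self.iterations <= 0:
            raise ValidationError("iteration budget must be positive")


def ndo_sigma(error: float, cfg: NDOConfig) -> float:
    """Perturbation scale sigma(e): linear in e, saturating at e0."""
    return cfg.sigma_min + (cfg.sigma_max - cfg.sigma_min) * min(error / cfg.e0, 1.0)


def ndo_propose(reference: np.ndarray, reference_error: float,
                cfg: NDOConfig, rng: np.random.Generator) -> np.ndarray:
    """Perturb the reference by iid normal noise, clipped to [0, 1]."""
    if reference_error < 0:
        raise ValidationError("reference error must be >= 0")
    sigma = ndo_sigma(reference_error, cfg)
    return np.clip(reference + rng.normal(0.0, sigma, size=reference.shape), 0.0, 1.0)


@dataclass
class OptimisationTrace:
    restart: int
    params: list = field(default_factory=list)
    errors: list = field(default_factory=list)
    best_params: np.ndarray | None = None
    best_error: float = np.inf

    def record(self, x: np.ndarray, e: float) -> None:
        self.params.append(np.asarray(x).copy())
        self.errors.append(float(e))
        if e < self.best_error:
            self.best_error = float(e)
            self.best_params = np.asarray(x).copy()

    @property
    def best_so_far(self) -> np.ndarray:
        """Running minimum of the error sequence (non-increasing)."""
        return np.minimum.accumulate(self.errors)


class FeasibleRegionGrid:
    """Coarse map of visited parameter space: 16 bins per dimension.

    Each visited bin keeps the lowest error seen there with its
    parameters and a visit count — the exhaustiveness monitor for the
    random-restart search.
    """

    def __init__(self, d: int, bins: int = GRID_BINS):
        self.d = d
        self.bins = bins
        self.cells: dict[tuple, tuple[float, np.ndarray, int]] = {}

    def bin_index(self, params: np.ndarray) -> tuple:
        idx = np.minimum((self.bins * np.asarray(params)).astype(int), self.bins - 1)
        return tuple(int(i) for i in idx)

    def record(self, params: np.ndarray, error: float) -> None:
        key = self.bin_index(params)
        prev = self.cells.get(key)
        if prev is None:
            self.cells[key] = (float(error), np.asarray(params).copy(), 1)
        else:
            e0, p0, c = prev
            if error < e0:
                self.cells[key] = (float(error), np.asarray(params).copy(), c + 1)
            else:
                self.cells[key] = (e0, p0, c + 1)

    def coverage(self) -> int:
        return len(self.cells)

    def feasible_cells(self, threshold: float) -> dict:
        return {k: v for k, v in self.cells.items() if v[0] <= threshold}


def record_feasible(grid: FeasibleRegionGrid, params, error) -> FeasibleRegionGrid:
    grid.record(np.asarray(params, dtype=float), float(error))
    return grid


def ndo_optimise(objective: Callable[[np.ndarray], float], d: int,
                 cfg: NDOConfig, n_restarts: int = 1,
                 threshold: float = 0.05,
                 grid: FeasibleRegionGrid | None = None,
                 rng: np.random.Generator | None = None):
    """Random-restart NDO over the unit hypercube.

    Per restart: uniform random initialisation, then a fixed iteration
    budget of propose-and-accept-on-strict-improvement steps from the
    lowest-error reference.  Every evaluated point is recorded into the
    feasible-region grid.  Returns (traces, feasible) where ``feasible``
    lists all (params, error) pairs with error <= threshold.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if grid is None:
        grid = FeasibleRegionGrid(d)
    traces: list[OptimisationTrace] = []
    feasible: list[tuple[np.ndarray, float]] = []

    for r in range(n_restarts):
        trace = OptimisationTrace(restart=r)
        x = rng.uniform(0.0, 1.0, size=d)
        e = float(objective(x))
        trace.record(x, e)
        grid.record(x, e)
        if e <= threshold:
            feasible.append((x.copy(), e))
        for _ in range(cfg.iterations):
            cand = ndo_propose(trace.best_params, trace.best_error, cfg, rng)
            ec = float(objective(cand))
            trace.record(cand, ec)
            grid.record(cand, ec)
            if ec <= threshold:
                feasible.append((cand.copy(), ec))
        traces.append(trace)
    return traces, feasible, grid


def traces_to_frame(traces, names):
    """Flatten optimisation traces into a tidy table (TSV-ready)."""
    import pandas as pd

    rows = []
    for tr in traces:
        for it, (x, e) in enumerate(zip(tr.params, tr.errors)):
            row = {"restart": tr.restart, "iteration": it, "error": e}
            row.update({nm: v for nm, v in zip(names, x)})
            rows.append(row)
    return pd.DataFrame(rows)


def hessian_sensitivity(objective: Callable[[np.ndarray], float],
                        params: np.ndarray, step: float = 1e-3):
    """Local sensitivity from the finite-difference Hessian.

    Returns (eigenvalues, eigenvectors) of the symmetric central-
    difference Hessian, sorted by decreasing |eigenvalue|; the leading
    eigenvector is the locally most error-sensitive parameter direction.
    """
    x = np.asarray(params, dtype=float)
    d = x.size
    if np.any(x - step < 0) or np.any(x + step > 1):
        raise ValidationError("params must be interior to [0,1]^d at the given step")
    f0 = objective(x)
    H = np.empty((d, d))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (objective(x + ei) - 2 * f0 + objective(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                objective(x + ei + ej) - objective(x + ei - ej)
                - objective(x - ei + ej) + objective(x - ei - ej)
            ) / (4 * step**2)
    if not np.all(np.isfinite(H)):
        raise ValidationError("non-finite Hessian entries; reduce the step")
    w, V = np.linalg.eigh(H)
    order = np.argsort(-np.abs(w))
    return w[order], V[:, order]
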