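"""Six identification error functionals and the comparison protocol.

Given reference data generated from one true parameter set, each method
scores how far a candidate rate system is from explaining those data:

* ``Freq1D``  — scaled-L1 distance between 1D molecule histograms;
* ``Freq2D``  — the same contract on the flattened labelled/total table
  (metabolic labelling);
* ``RatesPAV`` — deviation of population-averaged production/degradation
  rates, with the reference rates estimated from labelled/unlabelled
  totals via the exponential-decay labelling estimators;
* ``RatesSCTid`` / ``RatesSCT`` — deviation from per-state rates
  reconstructed from single-cell tracking events (exact event times vs
  frame-sampled pseudo-events), weighted by state occupancy;
* ``LogLikeSCT`` — negative log-likelihood of the tracking data under
  the candidate's continuous-time jump process.

The protocol scores a common candidate set under all methods, scales the
rate/likelihood methods onto the Freq2D error range, and summarises
identifiability by minimum-error-vs-parameter-distance profiles and
per-parameter spreads of the low-error candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .identify import histogram_error
from .population import CellCycleConfig
from .rates import ParameterVector, RateSystem, ValidationError, unscale_parameters
from .synth import (Labelled2DDistribution, LabellingDesign, SCTTrajectory,
                    equilibrium_histogram, frames_from_trajectory,
                    simulate_labelling, simulate_sct)

METHODS = ("Freq1D", "Freq2D", "RatesPAV", "RatesSCTid", "RatesSCT", "LogLikeSCT")


# ---------------------------------------------------------------------
# individual error functionals
# ---------------------------------------------------------------------

def error_freq2d(sim, ref) -> float:
    """Scaled-L1 error on flattened (n, l) tables, averaged over times."""
    if isinstance(sim, Labelled2DDistribution):
        sim, ref = [sim], [ref]
    sims = [s.table().ravel() if isinstance(s, Labelled2DDistribution) else np.ravel(s)
            for s in sim]
    refs = [r.table().ravel() if isinstance(r, Labelled2DDistribution) else np.ravel(r)
            for r in ref]
    return histogram_error(sims, refs)


def estimate_rates_pav(L: float, U: float, T0: float, delta: float,
                       M: float = 1.0) -> tuple[float, float]:
    """Exponential-model labelling estimators of per-cell rates.

    From the labelled total L and unlabelled total U at the end of a
    pulse of length ``delta`` (hours), starting from total T0:

        lambda_hat = -ln(U / T0) / delta          (molecular decay)
        alpha_hat  = lambda_hat * L / (1 - exp(-lambda_hat * delta))

    Population-averaged per-cell rates are then P_hat = alpha_hat / M
    and D_hat = lambda_hat * (T0 / M) (decay constant times the mean
    molecule count).  The zero-degradation limit U -> T0 gives
    lambda_hat = 0 and alpha_hat -> L / delta.
    """
    if T0 <= 0 or U <= 0:
        raise ValidationError("need positive unlabelled totals (U > 0, T0 > 0)")
    if U > T0:
        # sampling artifact: unlabelled pool cannot grow
        U = T0
    lam_hat = -np.log(U / T0) / delta
    x = lam_hat * delta
    if x < 1e-12:
        alpha_hat = L / delta
    else:
        alpha_hat = lam_hat * L / (1.0 - np.exp(-x))
    return alpha_hat / M, lam_hat * (T0 / M)


def reconstruct_rates_sct(trajectories: list[SCTTrajectory] | None, N: int,
                          frames: list[np.ndarray] | None = None,
                          delta: float | None = None):
    """Per-state frequentist rate reconstruction from tracking data.

    Ideal mode (``trajectories``): the total event rate at state n is
    the event count divided by the occupancy time — the quantity the
    exponential waiting-time histogram estimates — and is split between
    production and degradation by their relative event frequencies.
    Frame mode (``frames`` + ``delta``): pseudo-events are first read off
    successive frame differences (+c -> c productions, -c -> c
    degradations) and occupancy is the frame interval times the frames
    spent at n; an approximation that degrades as ``delta`` grows.

    Returns (P_hat, D_hat, G_hat, occupancy); states never occupied are
    NaN.
    """
    counts_p = np.zeros(N + 1)
    counts_d = np.zeros(N + 1)
    counts_g = np.zeros(N + 1)
    occ = np.zeros(N + 1)
    if trajectories is not None:
        for tr in trajectories:
            occ += tr.occupancy(N, 1)[:, 0]
            cc = tr.event_counts(N, ("production", "degradation", "growth", "division"))
            counts_p += cc["production"][:, 0]
            counts_d += cc["degradation"][:, 0]
            counts_g += cc["growth"][:, 0] + cc["division"][:, 0]
    elif frames is not None:
        if delta is None or delta <= 0:
            raise ValidationError("frame mode needs a positive frame interval")
        for fr in frames:
            fr = np.asarray(fr)
            occ += np.bincount(fr[:-1], minlength=N + 1)[: N + 1] * delta
            diffs = np.diff(fr)
            for n0, dn in zip(fr[:-1], diffs):
                if dn > 0:
                    counts_p[n0] += dn
                elif dn < 0:
                    counts_d[n0] += -dn
    else:
        raise ValidationError("supply trajectories or frames")
    if occ.sum() <= 0:
        raise ValidationError("zero total observation time")
    with np.errstate(divide="ignore", invalid="ignore"):
        P_hat = np.where(occ > 0, counts_p / occ, np.nan)
        D_hat = np.where(occ > 0, counts_d / occ, np.nan)
        G_hat = np.where(occ > 0, counts_g / occ, np.nan)
    return P_hat, D_hat, G_hat, occ


def sct_neg_loglik(rates: RateSystem, trajectories: list[SCTTrajectory],
                   cfg: CellCycleConfig | None = None) -> float:
    """Negative log-likelihood of tracking data under a candidate system.

    For a continuous-time jump process: minus the log event rates at the
    observed events plus the integrated total exit rate over the
    occupancy times.  A zero candidate rate at an observed event gives
    +inf (signalled, not raised).
    """
    cfg = cfg or CellCycleConfig()
    N, k = rates.N, cfg.k
    tables = rates.rate_tables(k)
    P = tables["P"].copy()
    P[N, :] = 0.0
    D = tables["D"].copy()
    D[0, :] = 0.0
    G = tables["G"]
    total = P + D + G
    nll = 0.0
    for tr in trajectories:
        occ = tr.occupancy(N, k)
        nll += float((occ * total).sum())
        for ev in tr.events:
            if ev.type == "production":
                r = P[ev.n_before, ev.phase - 1]
            elif ev.type == "degradation":
                r = D[ev.n_before, ev.phase - 1]
            else:
                r = G[ev.n_before, ev.phase - 1]
            if r <= 0:
                return np.inf
            nll -= np.log(r)
    return nll


def error_rates(est: tuple[np.ndarray, np.ndarray],
                ref_rates: RateSystem, weights: np.ndarray) -> float:
    """Occupancy-weighted mean absolute deviation between rate curves.

    ``est`` holds reconstructed (P_hat, D_hat) arrays on the molecule
    grid (NaN where undefined); the reference curves are evaluated on
    the same grid.  P and D deviations are averaged.
    """
    P_hat, D_hat = est
    n = np.arange(ref_rates.N + 1, dtype=float)
    P_ref, D_ref = ref_rates.P(n), ref_rates.D(n)
    w = np.asarray(weights, dtype=float)
    m = np.isfinite(P_hat) & np.isfinite(D_hat) & (w > 0)
    if not m.any():
        raise ValidationError("empty common support for rate comparison")
    wn = w[m] / w[m].sum()
    dev_p = float(wn @ np.abs(P_hat[m] - P_ref[m]))
    dev_d = float(wn @ np.abs(D_hat[m] - D_ref[m]))
    return 0.5 * (dev_p + dev_d)


# ---------------------------------------------------------------------
# reference data and the method battery
# ---------------------------------------------------------------------

@dataclass
class ReferenceDataset:
    """All data types generated from one true parameter set and seed."""

    true_params: ParameterVector
    rates: RateSystem
    cfg: CellCycleConfig
    design: LabellingDesign
    hist1d: np.ndarray
    labelled: list[Labelled2DDistribution]
    pav_estimate: tuple[float, float]
    trajectories: list[SCTTrajectory]
    frames: list[np.ndarray]
    frame_interval: float
    sct_weights: np.ndarray
    seed: int


def make_reference(rates: RateSystem, true_params: ParameterVector,
                   seed: int, cfg: CellCycleConfig | None = None,
                   design: LabellingDesign | None = None,
                   n_cells: int = 50, duration: float = 20.0,
                   frame_interval: float = 0.1) -> ReferenceDataset:
    """Generate the full synthetic reference battery (zero growth)."""
    cfg = cfg or CellCycleConfig()
    design = design or LabellingDesign()
    rng = np.random.default_rng(seed)
    hist1d = equilibrium_histogram(rates, cfg)
    labelled = simulate_labelling(rates, design, cfg, init=hist1d)
    L, U, M = labelled[-1].totals()
    T0 = float(hist1d @ np.arange(rates.N + 1))
    pav = estimate_rates_pav(L, U, T0, design.interval, M)
    trajs = simulate_sct(rates, cfg, n_cells, duration, rng)
    frames = [frames_from_trajectory(tr, frame_interval) for tr in trajs]
    _, _, _, occ = reconstruct_rates_sct(trajs, rates.N)
    return ReferenceDataset(true_params, rates, cfg, design, hist1d, labelled,
                            pav, trajs, frames, frame_interval, occ, seed)


def candidate_pav(rates: RateSystem, hist: np.ndarray) -> tuple[float, float]:
    """Model-predicted population-averaged rates under a distribution."""
    n = np.arange(rates.N + 1, dtype=float)
    p = hist / hist.sum()
    return float(p @ rates.P(n)), float(p @ rates.D(n))


def method_error(method: str, candidate: RateSystem, ref: ReferenceDataset) -> float:
    """Evaluate one identification error functional for a candidate."""
    if method == "Freq1D":
        sim = equilibrium_histogram(candidate, ref.cfg)
        return histogram_error(sim, ref.hist1d)
    if method == "Freq2D":
        sim = simulate_labelling(candidate, ref.design, ref.cfg)
        return error_freq2d(sim, ref.labelled)
    if method == "RatesPAV":
        sim = equilibrium_histogram(candidate, ref.cfg)
        P_hat, D_hat = candidate_pav(candidate, sim)
        P_ref, D_ref = ref.pav_estimate
        return 0.5 * (abs(P_hat - P_ref) + abs(D_hat - D_ref))
    if method == "RatesSCTid":
        P_hat, D_hat, _, occ = reconstruct_rates_sct(ref.trajectories, ref.rates.N)
        return error_rates_candidate(candidate, P_hat, D_hat, occ)
    if method == "RatesSCT":
        P_hat, D_hat, _, occ = reconstruct_rates_sct(
            None, ref.rates.N, frames=ref.frames, delta=ref.frame_interval)
        return error_rates_candidate(candidate, P_hat, D_hat, occ)
    if method == "LogLikeSCT":
        return sct_neg_loglik(candidate, ref.trajectories, ref.cfg)
    raise ValidationError(f"unknown method {method!r}")


def error_rates_candidate(candidate: RateSystem, P_hat, D_hat, occ) -> float:
    """Occupancy-weighted MAD of a candidate's curves vs reconstructions."""
    n = np.arange(candidate.N + 1, dtype=float)
    m = np.isfinite(P_hat) & np.isfinite(D_hat) & (occ > 0)
    if not m.any():
        raise ValidationError("no reconstructed states to compare against")
    w = occ[m] / occ[m].sum()
    return 0.5 * float(w @ (np.abs(candidate.P(n)[m] - P_hat[m])
                            + np.abs(candidate.D(n)[m] - D_hat[m])))


def evaluate_methods(candidates: list[ParameterVector], ref: ReferenceDataset,
                     methods=METHODS) -> pd.DataFrame:
    """Score every candidate under every method (long-format table)."""
    rows = []
    for ci, pv in enumerate(candidates):
        cand = unscale_parameters(pv, ref.rates)
        for m in methods:
            rows.append({"candidate": ci, "method": m,
                         "error": method_error(m, cand, ref)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# cross-method scaling, distance profiles, parameter spreads
# ---------------------------------------------------------------------

def scale_to_reference(errors: dict[str, np.ndarray], reference: str = "Freq2D",
                       anchor_zero: bool = False) -> dict[str, np.ndarray]:
    """Affine per-method calibration onto the reference method's range.

    Each method's (min, max) over the shared candidate set is mapped to
    the reference's (min, max); with ``anchor_zero`` the minimum maps to
    zero instead.  Affine maps preserve the candidate ordering.
    """
    ref = np.asarray(errors[reference], dtype=float)
    lo_r, hi_r = (0.0 if anchor_zero else ref.min()), ref.max()
    out = {}
    for m, e in errors.items():
        e = np.asarray(e, dtype=float)
        lo, hi = e.min(), e.max()
        if hi - lo <= 0:
            raise ValidationError(f"constant error vector for {m}: degenerate scaling")
        out[m] = lo_r + (e - lo) * (hi_r - lo_r) / (hi - lo)
    return out


DEFAULT_EXCLUDE = ("PY3", "DY3")


def parameter_distance(pv: ParameterVector, true: ParameterVector,
                       exclude=DEFAULT_EXCLUDE) -> float:
    """Euclidean distance between 0/1-scaled parameter vectors.

    The third y-set points of P and D are excluded by default: they
    govern the scarcely populated upper molecule range and are poorly
    identifiable, so including them mostly adds noise to the distance
    axis.
    """
    keep = [i for i, nm in enumerate(true.names) if nm not in (exclude or ())]
    return float(np.linalg.norm(pv.values[keep] - true.values[keep]))


@dataclass
class ComparisonProfile:
    """Minimum-error curve over parameter distance for one method."""

    centers: np.ndarray
    values: np.ndarray
    window: float = 0.05
    percentile: float = 0.01


def distance_profile(candidates: list[ParameterVector], errors,
                     true: ParameterVector, exclude=DEFAULT_EXCLUDE,
                     window: float = 0.05, percentile: float = 0.01,
                     n_centers: int | None = None) -> ComparisonProfile:
    """Minimum-error profile: mean of the lowest ``percentile`` fraction
    of errors within centred distance windows of width ``window``."""
    if len(candidates) == 0:
        raise ValidationError("need at least one candidate")
    d = np.array([parameter_distance(pv, true, exclude) for pv in candidates])
    e = np.asarray(errors, dtype=float)
    if n_centers is None:
        n_centers = max(int(np.ceil(d.max() / window)) + 1, 1)
    centers = window * np.arange(n_centers)
    vals = np.full(n_centers, np.nan)
    for j, c in enumerate(centers):
        m = np.abs(d - c) <= window / 2
        if not m.any():
            continue
        ew = np.sort(e[m])
        n_low = max(int(np.ceil(percentile * ew.size)), 1)
        vals[j] = ew[:n_low].mean()
    return ComparisonProfile(centers, vals, window, percentile)


def parameter_spread(candidates: list[ParameterVector], errors,
                     true: ParameterVector,
                     threshold: float = 0.02) -> pd.DataFrame:
    """Five-number summary and bias per parameter over low-error candidates."""
    e = np.asarray(errors, dtype=float)
    sel = [pv for pv, ei in zip(candidates, e) if ei <= threshold]
    if not sel:
        raise ValidationError(f"no candidates below error threshold {threshold}")
    X = np.array([pv.values for pv in sel])
    rows = []
    for j, nm in enumerate(true.names):
        q = np.percentile(X[:, j], [0, 25, 50, 75, 100])
        rows.append({
            "parameter": nm, "min": q[0], "q1": q[1], "median": q[2],
            "q3": q[3], "max": q[4], "iqr": q[3] - q[1],
            "bias": q[2] - true.values[j], "n": X.shape[0],
        })
    return pd.DataFrame(rows).set_index("parameter")
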