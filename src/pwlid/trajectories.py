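"""Gene-wise rate/expression trajectory analysis for labelling time courses.

Each gene carries short time series of expression T, production rate P
and degradation rate D (population averages per cell).  The pipeline:
smoothing-spline interpolation with derivatives; the derived series
A = P - D (deterministic) and B = P + D (noise) and their time
derivatives DA, DB; Pearson correlations (corPD, corDADB, corPT, corDT)
with exhaustive permutation nulls; trend classification by regression
slope signs; complete-linkage clustering of standardised expression
trajectories at a correlation-distance cutoff; and within-cluster
variation of T, P and D as the diversity measure for regulation types.

A positive corDADB marks production-dominated regulation, a negative
one degradation-dominated regulation: when P and D share a common
component, the derivative of A follows whichever rate varies more.

A synthetic generator emulating an osmotic-stress-response-like data
set (co-regulated P and D with a sharp shared upregulation step, a
majority of genes with decreasing expression) supports end-to-end tests
without the original, non-deposited measurements.
"""

from __future__ import annotations

from itertools import permutations
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import make_smoothing_spline
from scipy.spatial.distance import squareform

from .rates import ValidationError

DEFAULT_TIMES = np.arange(0.0, 37.0, 6.0)  # 7 points, 6-min spacing (minutes)


@dataclass
class GeneTrajectory:
    """Per-gene time series: expression T, production P, degradation D."""

    gene: str
    times: np.ndarray  # minutes, strictly increasing
    T: np.ndarray
    P: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for nm in ("T", "P", "D"):
            v = np.asarray(getattr(self, nm), dtype=float)
            if v.shape != self.times.shape:
                raise ValidationError(f"{nm} length must match times")
            setattr(self, nm, v)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.P < 0) or np.any(self.D < 0):
            raise ValidationError("rates must be >= 0")


@dataclass
class DerivedSeries:
    A: np.ndarray
    B: np.ndarray
    DA: np.ndarray
    DB: np.ndarray


@dataclass
class CorrelationSet:
    corPD: float
    corDADB: float
    corPT: float
    corDT: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def smooth_series(times, values, lam: float | None = None):
    """Smoothing-spline fit; returns (fitted values, first derivative).

    The smoothing parameter is chosen by generalised cross-validation
    unless ``lam`` is given; on noiseless input the fit is close to
    interpolation and the derivative tracks the analytic one.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValidationError("smoothing needs at least 4 time points")
    spl = make_smoothing_spline(t, y, lam=lam)
    return spl(t), spl.derivative()(t)


def derive_AB(traj: GeneTrajectory, lam: float | None = None) -> DerivedSeries:
    """A = P - D, B = P + D and their smoothed time derivatives."""
    A = traj.P - traj.D
    B = traj.P + traj.D
    _, DA = smooth_series(traj.times, A, lam)
    _, DB = smooth_series(traj.times, B, lam)
    return DerivedSeries(A, B, DA, DB)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return np.nan  # undefined for constant series; reported missing
    return float(np.corrcoef(x, y)[0, 1])


def correlations(traj: GeneTrajectory, derived: DerivedSeries | None = None) -> CorrelationSet:
    derived = derived or derive_AB(traj)
    return CorrelationSet(
        corPD=_pearson(traj.P, traj.D),
        corDADB=_pearson(derived.DA, derived.DB),
        corPT=_pearson(traj.P, traj.T),
        corDT=_pearson(traj.D, traj.T),
    )


MAX_EXHAUSTIVE = 9  # 9! = 362880 permutations; beyond that, sample


def permutation_null(x, y, statistic=_pearson, mode: str = "exhaustive",
                     n_samples: int = 10000,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Null distribution of a pair statistic over time-order permutations.

    Exhaustive mode enumerates all m! orderings of the second series
    (equivalent in distribution to permuting either series); with m = 7
    time points this is exactly 5040 values, containing the observed
    statistic at the identity permutation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = x.size
    if mode == "exhaustive":
        if m > MAX_EXHAUSTIVE:
            raise ValidationError(
                f"{m}! permutations is too many to enumerate; use mode='sample'")
        return np.array([statistic(x, y[list(p)]) for p in permutations(range(m))])
    if mode == "sample":
        rng = rng or np.random.default_rng()
        return np.array([statistic(x, y[rng.permutation(m)]) for _ in range(n_samples)])
    raise ValidationError("mode must be 'exhaustive' or 'sample'")


def classify_trend(times, values) -> str:
    """Sign of the least-squares slope: '+' or '-' (zero counts as '+')."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValidationError("trend needs at least 2 points")
    slope = np.polyfit(t, v, 1)[0]
    return "+" if slope >= 0 else "-"


def trend_labels(traj: GeneTrajectory) -> dict[str, str]:
    return {nm: classify_trend(traj.times, getattr(traj, nm)) for nm in ("T", "P", "D")}


def standardise(series: np.ndarray) -> np.ndarray:
    """Mean 0, standard deviation 1 across time (population sd)."""
    s = np.asarray(series, dtype=float)
    sd = s.std()
    if sd == 0:
        raise ValidationError("constant series cannot be standardised")
    return (s - s.mean()) / sd


@dataclass
class ClusterSet:
    labels: np.ndarray        # cluster id per kept gene
    kept: np.ndarray          # indices of genes that were clusterable
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)

    def members(self) -> dict[int, np.ndarray]:
        return {int(c): self.kept[self.labels == c] for c in np.unique(self.labels)}


def cluster_trajectories(T_matrix: np.ndarray, cutoff: float = 0.15) -> ClusterSet:
    """Complete-linkage clustering of standardised expression trajectories.

    Distance d = 1 - Pearson(T_a, T_b): anti-correlated profiles are
    biologically distinct regulation, hence maximally distant (d = 2).
    The dendrogram is cut at ``cutoff`` so that every within-cluster
    pair correlates at r >= 1 - cutoff.  Constant trajectories are
    excluded (their correlation is undefined).
    """
    T = np.asarray(T_matrix, dtype=float)
    if T.ndim != 2 or T.shape[0] < 2:
        raise ValidationError("need at least 2 gene trajectories")
    sd = T.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < T.shape[0]:
        import warnings

        warnings.warn(f"excluded {T.shape[0] - kept.size} constant trajectories")
    Z = (T[kept] - T[kept].mean(axis=1, keepdims=True)) / sd[kept, None]
    corr = np.corrcoef(Z)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    labels = fcluster(linkage(squareform(dist, checks=False), method="complete"),
                      t=cutoff, criterion="distance")
    return ClusterSet(labels, kept, cutoff)


def within_cluster_variation(clusters: ClusterSet,
                             series: dict[str, np.ndarray],
                             times=None) -> pd.DataFrame:
    """Mean within-cluster standard deviation per series type.

    For every cluster with >= 2 members and every series type (e.g. T,
    P, D as standardised gene x time matrices): the sd (ddof=1) across
    member genes is taken at each time point first, then averaged across
    time.  The cluster's expression trend (least-squares slope of its
    mean standardised T course) is attached so variation can be
    regressed against the trend.  Singleton clusters are excluded.
    """
    rows = []
    T_mat = series.get("T")
    for cid, members in clusters.members().items():
        if members.size < 2:
            continue
        row = {"cluster": cid, "size": int(members.size)}
        if T_mat is not None:
            mean_T = T_mat[members].mean(axis=0)
            t = np.arange(mean_T.size, dtype=float) if times is None else np.asarray(times, float)
            row["trend"] = float(np.polyfit(t, mean_T, 1)[0])
        for nm, mat in series.items():
            sd_t = np.std(mat[members], axis=0, ddof=1)
            row[f"sd_{nm}"] = float(sd_t.mean())
        rows.append(row)
    if not rows:
        raise ValidationError("all clusters are singletons")
    return pd.DataFrame(rows).set_index("cluster")


def variation_regression(var_table: pd.DataFrame, series_names=("T", "P", "D")) -> dict:
    """Least-squares line of within-cluster sd against the cluster trend."""
    out = {}
    for nm in series_names:
        col = f"sd_{nm}"
        if col in var_table and "trend" in var_table:
            slope, intercept = np.polyfit(var_table["trend"], var_table[col], 1)
            out[nm] = {"slope": float(slope), "intercept": float(intercept)}
    return out


# ---------------------------------------------------------------------
# synthetic yeast-like generator
# ---------------------------------------------------------------------

ARCHETYPES = ("T-Ddom", "T-Pdom", "T+Pdom", "T+Ddom")
DEFAULT_WEIGHTS = (0.37, 0.29, 0.22, 0.12)
# T-/T+ split 66/34; Ddom/Pdom marks whether degradation or production
# takes the larger share of the shared upregulation step


def synth_yeast(n_genes: int = 2000, weights=DEFAULT_WEIGHTS,
                noise_sd: float = 0.05, smooth_sd: float = 0.2,
                seed: int | None = None, times=None) -> list[GeneTrajectory]:
    """Synthetic co-regulated P/D/T trajectories with known archetypes.

    Each gene draws an archetype: decreasing (T-) or increasing (T+)
    expression, dominated by degradation (D) or production (P)
    variability.  P and D share one common upregulation-step component
    (logistic step centred between minutes 12 and 18) so they are
    perfectly correlated before noise; the dominance is set by which
    rate takes the larger step amplitude, and the expression trend by
    the sign of the mean production-degradation offset.  On top of the
    shared step each rate carries an independent smooth low-order
    component of scale ``smooth_sd``, which diversifies the expression
    shapes into many clusters (as real time courses do); set it to zero
    for pure archetypes with corPD = 1.  T integrates dT/dt
    proportional to P - D from a positive baseline.  Gaussian
    observation noise of ``noise_sd`` (same units as the rates,
    events/h of order 1) is added to P, D and (scaled) T.
    """
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValidationError("archetype weights must sum to 1")
    rng = np.random.default_rng(seed)
    t = DEFAULT_TIMES if times is None else np.asarray(times, dtype=float)
    step = 1.0 / (1.0 + np.exp(-(t - 15.0) / 1.5))  # shared upregulation
    genes = []
    arch_idx = rng.choice(len(ARCHETYPES), size=n_genes, p=np.asarray(weights))
    for g in range(n_genes):
        arch = ARCHETYPES[arch_idx[g]]
        amp = rng.uniform(1.0, 2.0)      # step amplitude of the dominant rate
        ratio = rng.uniform(0.3, 0.6)    # subordinate/dominant amplitude
        base = rng.uniform(1.0, 2.0)
        if "Ddom" in arch:               # degradation-dominated variability
            a_d, a_p = amp, amp * ratio
        else:
            a_p, a_d = amp, amp * ratio
        # baseline offset large enough that dT/dt keeps one sign, so the
        # expression trend is the archetype's by construction
        margin = rng.uniform(0.3, 0.8)
        if arch.startswith("T-"):
            p0, d0 = base, base + margin + max(a_p - a_d, 0.0)
        else:
            p0, d0 = base + margin + max(a_d - a_p, 0.0), base
        u = (t - t.mean()) / (t[-1] - t[0]) * 2.0  # [-1, 1]
        basis = np.stack([u, u**2 - u.mean()**2, np.sin(np.pi * u)])
        P = p0 + a_p * step + smooth_sd * (rng.normal(size=3) @ basis)
        D = d0 + a_d * step + smooth_sd * (rng.normal(size=3) @ basis)
        dt_min = np.gradient(t)
        T = 50.0 + np.cumsum((P - D) * dt_min) * 0.25  # arbitrary positive scale
        P = np.clip(P + rng.normal(0, noise_sd, t.size), 0, None)
        D = np.clip(D + rng.normal(0, noise_sd, t.size), 0, None)
        T = T + rng.normal(0, noise_sd * 2.0, t.size)
        genes.append(GeneTrajectory(f"g{g:05d}_{arch}", t, T, P, D))
    return genes


def analyse_genes(genes: list[GeneTrajectory], cutoff: float = 0.15) -> pd.DataFrame:
    """Per-gene correlations, trend labels and cluster assignment."""
    rows = []
    for g in genes:
        cs = correlations(g)
        row = {"gene": g.gene, **cs.as_dict(), **{f"trend_{k}": v
               for k, v in trend_labels(g).items()}}
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene")
    T = np.array([standardise(g.T) for g in genes])
    clusters = cluster_trajectories(T, cutoff)
    col = np.full(len(genes), -1)
    col[clusters.kept] = clusters.labels
    df["cluster"] = col
    return df
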