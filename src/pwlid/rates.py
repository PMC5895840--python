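"""Piecewise-linear rate functions and their scaled parameterisation.

Production (P), degradation (D) and growth (G) rates over the molecule
number n, and the induction curve I(t) over time, are all represented as
set-point curves: linear interpolation between a small number of
(x, y) set points, constant extrapolation right of the last set point.
This family can approximate any continuous rate law (constant, linear,
Michaelis-Menten, non-monotonous) without committing to one a priori,
which is the whole point of the identification machinery built on top.

Conventions baked into the curve kinds:

* ``production`` / ``degradation``: three free y-set points, capped at
  ``RATE_CAP`` = 12 events/h.  Degradation carries an implicit anchor at
  (0, 0) — a cell with no molecules cannot degrade one.
* ``growth``: non-decreasing in n, capped at ln(2)/2 per hour
  (a 2 h minimum doubling time); the last y-set point is conventionally
  fixed at the cap, leaving two free parameters.
* ``induction``: dimensionless blending weight in [0, 1] over time, with
  an implicit anchor at (0, 0) and terminal value 1 right of the last
  time set point; two free parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

RATE_CAP = 12.0               # events/h, for production and degradation
GROWTH_CAP = math.log(2) / 2  # per hour, 2 h minimum doubling time

_CAPS = {
    "production": RATE_CAP,
    "degradation": RATE_CAP,
    "growth": GROWTH_CAP,
    "induction": 1.0,
}

KINDS = tuple(_CAPS)


class ValidationError(ValueError):
    """A curve or parameter vector violates its structural invariants."""


class DomainError(ValueError):
    """Evaluation requested outside the admissible molecule-number range."""


@dataclass
class SetPointCurve:
    """A piecewise-linear curve defined by strictly increasing set points.

    Parameters
    ----------
    kind
        One of ``production``, ``degradation``, ``growth``, ``induction``.
    x_points, y_points
        Abscissae (molecule number, or hours for induction) and ordinates
        (events/h, or a dimensionless weight for induction).
    cap
        Upper bound on the curve value.  ``None`` (default) means the
        kind's conventional cap; ``math.inf`` disables the cap (used
        e.g. for uncapped linear degradation in the classical
        birth-death special case).
    """

    kind: str
    x_points: np.ndarray
    y_points: np.ndarray
    cap: float | None = None
    _x: np.ndarray = field(init=False, repr=False)
    _y: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown curve kind {self.kind!r}")
        self.x_points = np.asarray(self.x_points, dtype=float)
        self.y_points = np.asarray(self.y_points, dtype=float)
        if self.cap is None:
            self.cap = _CAPS[self.kind]
        x, y = self.x_points, self.y_points
        if x.ndim != 1 or x.shape != y.shape or x.size < 1:
            raise ValidationError("x_points and y_points must be equal-length 1D arrays")
        if np.any(np.diff(x) <= 0):
            raise ValidationError("x_points must be strictly increasing")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise ValidationError("y_points must be finite and >= 0")
        if np.any(y > self.cap + 1e-12):
            raise ValidationError(
                f"{self.kind} y-set points exceed the cap {self.cap:g}"
            )
        if self.kind in ("growth", "induction") and np.any(np.diff(y) < 0):
            raise ValidationError(f"{self.kind} curve must be non-decreasing")
        if self.kind == "induction" and x[0] <= 0:
            raise ValidationError("induction time set points must be positive")
        # anchored variants: degradation at (0,0); induction at (0,0)
        if self.kind in ("degradation", "induction") and x[0] > 0:
            self._x = np.concatenate(([0.0], x))
            self._y = np.concatenate(([0.0], y))
            if self.kind == "degradation" and x[0] == 0 and y[0] != 0:
                raise ValidationError("degradation is anchored at D(0)=0")
        else:
            self._x, self._y = x, y

    def __call__(self, n):
        """Evaluate the curve; constant extrapolation on both sides.

        Left of the first stored point production/growth stay constant at
        the first ordinate; degradation and induction interpolate up from
        their (0, 0) anchors (already folded into the stored points).
        """
        val = np.interp(n, self._x, self._y)
        return np.clip(val, 0.0, self.cap)

    @property
    def terminal_value(self) -> float:
        return float(self._y[-1])

    def with_y(self, y_points) -> "SetPointCurve":
        return SetPointCurve(self.kind, self.x_points.copy(), np.asarray(y_points, float), self.cap)

    def scaled(self, factor: float) -> "SetPointCurve":
        """Multiply all y-set points by ``factor`` (cap still enforced)."""
        return self.with_y(self.y_points * factor)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "x_points": self.x_points.tolist(),
            "y_points": self.y_points.tolist(),
        }
        if self.cap != _CAPS[self.kind]:
            d["cap"] = float(self.cap)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SetPointCurve":
        return cls(d["kind"], d["x_points"], d["y_points"], d.get("cap"))


def default_x_points(N: int) -> np.ndarray:
    """Equidistant non-boundary x-set points for an N-molecule range.

    Equidistant interior positions give the y-set points equal influence
    on the curve, which keeps the scaled parameters comparably sensitive.
    """
    return np.round(np.array([N / 6, N / 2, 5 * N / 6]))


def evaluate_rate(curve: SetPointCurve, n, N: int | None = None):
    """Evaluate a rate curve at molecule number(s) ``n``.

    With ``N`` given, n outside [0, N] raises :class:`DomainError`.
    """
    n = np.asarray(n, dtype=float)
    if N is not None and (np.any(n < 0) or np.any(n > N)):
        raise DomainError(f"molecule number outside [0, {N}]")
    out = curve(n)
    return float(out) if out.ndim == 0 else out


def cell_volume(i, k: int):
    """Relative cell volume v_i = 1 + (i-1)/(k-1) for phase i of k."""
    if k < 2:
        raise ValidationError("cell-cycle phase count k must be >= 2")
    return 1.0 + (np.asarray(i, dtype=float) - 1.0) / (k - 1)


def dilution_lookup(curve: SetPointCurve, n, i: int, k: int):
    """Volume-corrected rate lookup R(n, i) = R(floor(n / v_i)).

    Rates are functions of concentration; as the cell swells from volume
    1 (phase 1) to 2 (phase k) the same molecule number corresponds to a
    lower concentration, hence the floored division before lookup.
    """
    v = cell_volume(i, k)
    if np.any(np.asarray(n) < 0):
        raise DomainError("molecule number must be >= 0")
    return evaluate_rate(curve, np.floor(np.asarray(n, dtype=float) / v))


@dataclass
class RateSystem:
    """Production/degradation/growth rate curves on molecule range [0, N]."""

    P: SetPointCurve
    D: SetPointCurve
    G: SetPointCurve | float
    N: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValidationError("N must be >= 1")
        if isinstance(self.G, (int, float)):
            g = float(self.G)
            if not 0.0 <= g <= GROWTH_CAP + 1e-12:
                raise ValidationError(f"constant growth rate outside [0, {GROWTH_CAP:g}]")
        for name in ("P", "D", "G"):
            c = getattr(self, name)
            if isinstance(c, SetPointCurve) and (
                np.any(c.x_points < 0) or np.any(c.x_points > self.N)
            ):
                raise ValidationError(f"{name} x-set points outside [0, {self.N}]")

    # -- evaluation ---------------------------------------------------
    def growth(self, n):
        if isinstance(self.G, SetPointCurve):
            return self.G(n)
        return np.full_like(np.asarray(n, dtype=float), float(self.G))

    def rate_tables(self, k: int) -> dict[str, np.ndarray]:
        """Dilution-corrected rate matrices of shape (N+1, k).

        Entry [n, i-1] is R(floor(n / v_i)) for R in P, D, G.
        """
        n = np.arange(self.N + 1, dtype=float)
        v = cell_volume(np.arange(1, k + 1), k)
        idx = np.floor(n[:, None] / v[None, :])
        gcurve = self.G if isinstance(self.G, SetPointCurve) else None
        tables = {
            "P": self.P(idx),
            "D": self.D(idx),
            "G": gcurve(idx) if gcurve is not None else np.full(idx.shape, float(self.G)),
        }
        return tables

    def has_growth(self) -> bool:
        if isinstance(self.G, SetPointCurve):
            return bool(np.any(self.G.y_points > 0))
        return float(self.G) > 0

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        g = self.G.to_dict() if isinstance(self.G, SetPointCurve) else float(self.G)
        return {"N": int(self.N), "P": self.P.to_dict(), "D": self.D.to_dict(), "G": g}

    @classmethod
    def from_dict(cls, d: dict) -> "RateSystem":
        g = d["G"]
        if isinstance(g, dict):
            g = SetPointCurve.from_dict(g)
        return cls(SetPointCurve.from_dict(d["P"]), SetPointCurve.from_dict(d["D"]), g, int(d["N"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RateSystem":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def pwl_system(N: int, p_y, d_y, g_y=0.0, x_points=None) -> RateSystem:
    """Build a standard three-set-point P/D system on [0, N].

    ``g_y`` may be a constant growth rate or a pair of free growth
    y-set points (the third is fixed at the growth cap).
    """
    x = default_x_points(N) if x_points is None else np.asarray(x_points, float)
    P = SetPointCurve("production", x, p_y)
    D = SetPointCurve("degradation", x, d_y)
    if isinstance(g_y, (int, float)):
        G: SetPointCurve | float = float(g_y)
    else:
        g_y = np.asarray(g_y, dtype=float)
        if g_y.size == 2:
            g_y = np.concatenate([g_y, [GROWTH_CAP]])
        G = SetPointCurve("growth", x, g_y)
    return RateSystem(P, D, G, N)


def birth_death_system(alpha: float, lam: float, N: int,
                       cap: float = math.inf) -> RateSystem:
    """Classical birth-death process: constant production alpha,
    linear degradation D(n) = lam * n, zero growth.

    The linear degradation is represented exactly by collinear set points
    with the last x-set point at N (beyond which the curve is constant,
    which is outside the domain).  ``cap=None`` disables the 12/h cap,
    which D(N) = lam*N typically exceeds; the default disables it.
    """
    x = np.array([N / 3, 2 * N / 3, N], dtype=float)
    P = SetPointCurve("production", x, np.full(3, alpha), cap=cap)
    D = SetPointCurve("degradation", x, lam * x, cap=cap)
    return RateSystem(P, D, 0.0, N)


# ---------------------------------------------------------------------
# induction blending
# ---------------------------------------------------------------------

DEFAULT_INDUCTION_TIMES = np.array([0.5, 2.0, 5.0])


@dataclass
class InductionSchedule:
    """Time-dependent blend between two rate systems.

    ``I(t)`` in [0, 1] transforms the equilibrium rates of the fast-
    proliferation state ``fast`` into those of the activated state
    ``slow``:  R(n, t) = R_fast(n) * (1 - I(t)) + R_slow(n) * I(t).
    """

    I: SetPointCurve
    fast: RateSystem
    slow: RateSystem

    def __post_init__(self) -> None:
        if self.I.kind != "induction":
            raise ValidationError("schedule curve must have kind='induction'")
        if self.fast.N != self.slow.N:
            raise ValidationError("fast and slow systems must share N")

    @property
    def N(self) -> int:
        return self.fast.N

    def weight(self, t: float) -> float:
        w = float(self.I(t))
        if not 0.0 <= w <= 1.0:
            raise ValidationError("induction weight outside [0, 1]")
        return w


def induction_curve(y_free, time_points=None) -> SetPointCurve:
    """Induction curve with anchors I(0)=0 and terminal value 1.

    ``y_free`` are the two free y-set points; the third is fixed at 1.
    """
    t = DEFAULT_INDUCTION_TIMES if time_points is None else np.asarray(time_points, float)
    y_free = np.asarray(y_free, dtype=float)
    if y_free.size == 2:
        y = np.concatenate([y_free, [1.0]])
    else:
        y = y_free
    if y[-1] != 1.0:
        raise ValidationError("induction terminal value must be 1")
    return SetPointCurve("induction", t, y)


def blend_rates(schedule: InductionSchedule, n, t: float):
    """Induction-blended production and degradation rates at (n, t)."""
    if t < 0:
        raise DomainError("time must be >= 0")
    w = schedule.weight(t)
    P = (1 - w) * schedule.fast.P(n) + w * schedule.slow.P(n)
    D = (1 - w) * schedule.fast.D(n) + w * schedule.slow.D(n)
    return P, D


# ---------------------------------------------------------------------
# scaled parameter vectors
# ---------------------------------------------------------------------

_PD_NAMES = ("PY1", "PY2", "PY3", "DY1", "DY2", "DY3")
_G_NAMES = ("GY1", "GY2")
_I_NAMES = ("IY1", "IY2")


@dataclass
class ParameterVector:
    """Named 0/1-scaled y-set points (PY1..PY3, DY1..DY3, GY1, GY2, IY1, IY2).

    Scaling divides each physical y-value by its curve's cap, so every
    component lives in [0, 1] and the optimiser can treat the parameter
    space as the unit hypercube.
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValidationError("names/values length mismatch")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValidationError("scaled components must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(self.names, self.values)}

    @property
    def d(self) -> int:
        return self.values.size


def scale_parameters(rates: RateSystem, schedule_I: SetPointCurve | None = None) -> ParameterVector:
    """Map a rate system to its 0/1-scaled free-parameter vector."""
    cap_pd = rates.P.cap if math.isfinite(rates.P.cap) else RATE_CAP
    names: list[str] = list(_PD_NAMES)
    vals = list(rates.P.y_points / cap_pd) + list(rates.D.y_points / cap_pd)
    if isinstance(rates.G, SetPointCurve):
        names += list(_G_NAMES)
        vals += list(rates.G.y_points[:2] / GROWTH_CAP)
    if schedule_I is not None:
        names += list(_I_NAMES)
        vals += list(schedule_I.y_points[:2])
    return ParameterVector(tuple(names), np.array(vals))


def unscale_parameters(pv: ParameterVector, template: RateSystem) -> RateSystem:
    """Rebuild a rate system from scaled parameters on a template's grid."""
    cap_pd = template.P.cap if math.isfinite(template.P.cap) else RATE_CAP
    v = pv.as_dict()
    P = template.P.with_y([v["PY1"] * cap_pd, v["PY2"] * cap_pd, v["PY3"] * cap_pd])
    D = template.D.with_y([v["DY1"] * cap_pd, v["DY2"] * cap_pd, v["DY3"] * cap_pd])
    if isinstance(template.G, SetPointCurve) and "GY1" in v:
        # monotonicity is a constraint, not silently repaired: with_y
        # raises ValidationError if GY1 > GY2
        g_y = np.array([v["GY1"], v["GY2"]]) * GROWTH_CAP
        G: SetPointCurve | float = template.G.with_y(np.concatenate([g_y, [GROWTH_CAP]]))
    else:
        G = template.G
    return RateSystem(P, D, G, template.N)
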