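"""Nullcline construction, fixed points, bistability, and parameter sweeps.

The long-term behavior of the full model projects onto the (cs, c) plane:

* the c-nullcline solves ``0 = q0*I*h(cs) + gc(c) - q2*c`` and is computed
  in closed form per ``c``: with ``u = (q2*c - gc(c)) / (q0*I)``, a point
  exists iff ``0 <= u < 1`` and then ``cs = -ln(1-u)/k``.  For a
  sufficiently large Hill coefficient the curve is S-shaped (folded), and
  its two knees bound the bistable window in ``cs``;
* the cs-nullcline replaces the oscillating cortisol by its cycle average
  over the PA attractor: ``cs = c_inf_bar + <exp(-b o)>(c)``.

Intersections of the two curves are the system's long-term states; with a
fold, two stable intersections (normal = higher cortisol, diseased = lower)
bracket an unstable one.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .model import SystemState, autocrine_upregulation, release_fraction
from .pa import LimitCycleSummary, characterize
from .parameters import ParameterSet
from .solver import DEFAULT_STEP, constant_history, integrate

__all__ = [
    "NullclineCurve",
    "FixedPoint",
    "c_nullcline",
    "cs_nullcline",
    "find_fixed_points",
    "sweep",
    "c_nullcline_cs_of_c",
    "curve_summary",
]

_DEFAULT_CS_GRID_POINTS = 41


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullclineCurve:
    """A sampled nullcline in the (cs, c) plane, ordered by increasing c.

    ``branch_labels`` partitions a folded c-nullcline into lower / middle /
    upper branches at its knees (an unfolded curve is all "lower").  For a
    cs-nullcline, ``oscillatory`` flags the samples whose underlying PA
    attractor is a limit cycle (the period-averaged stretch of the curve),
    and ``mean_o`` carries the attractor cortisol average per sample.
    """

    which: str  # "c_nullcline" | "cs_nullcline"
    c: np.ndarray
    cs: np.ndarray
    knees: tuple[tuple[float, float], ...] = ()  # (cs, c) fold points
    branch_labels: np.ndarray | None = None
    oscillatory: np.ndarray | None = None
    mean_o: np.ndarray | None = None

    @property
    def is_empty(self) -> bool:
        return self.c.size == 0

    @property
    def folded(self) -> bool:
        return len(self.knees) > 0

    def cs_at(self, c: float) -> float:
        """Linear interpolation of cs along the curve."""
        return float(np.interp(c, self.c, self.cs))

    def oscillatory_c_range(self) -> tuple[float, float] | None:
        if self.oscillatory is None or not np.any(self.oscillatory):
            return None
        cs = self.c[self.oscillatory]
        return float(cs.min()), float(cs.max())


def c_nullcline_cs_of_c(c: float | np.ndarray, params: ParameterSet) -> float | np.ndarray:
    """Closed-form cs on the c-nullcline at given c (NaN where no point exists)."""
    c_arr = np.asarray(c, dtype=float)
    u = (params.q2 * c_arr - autocrine_upregulation(c_arr, params)) / (params.q0 * params.I0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cs = np.where((u >= 0) & (u < 1), -np.log1p(-np.clip(u, None, 1 - 1e-300)) / params.k, np.nan)
    return float(cs) if cs.ndim == 0 else cs


def _c_domain_end(params: ParameterSet) -> float:
    """Largest c for which the c-nullcline exists (u(c) reaches 1)."""
    def u(cv: float) -> float:
        return (params.q2 * cv - autocrine_upregulation(cv, params)) / (params.q0 * params.I0)
    hi = 1.0
    while u(hi) < 1.0:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("could not bracket the end of the c-nullcline domain")
    lo = hi / 2.0
    return brentq(lambda cv: u(cv) - 1.0, lo, hi, xtol=1e-10)


def _detect_knees(c: np.ndarray, cs: np.ndarray) -> tuple[tuple[float, float], ...]:
    """Fold points as local extrema of cs along the curve (3-point stencil)."""
    if c.size < 5:
        return ()
    slope = np.gradient(cs, c)
    sgn = np.sign(slope)
    flips = np.nonzero(sgn[1:-1] * sgn[2:] < 0)[0] + 1
    knees = []
    for i in flips:
        # parabola through the three samples around the extremum
        j = min(max(i, 1), c.size - 2)
        x0, x1, x2 = c[j - 1], c[j], c[j + 1]
        y0, y1, y2 = cs[j - 1], cs[j], cs[j + 1]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a_coef = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b_coef = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
        if a_coef != 0:
            c_star = -b_coef / (2 * a_coef)
            if not (x0 <= c_star <= x2):
                c_star = x1
        else:
            c_star = x1
        cs_star = float(np.interp(c_star, c, cs))
        knees.append((cs_star, float(c_star)))
    return tuple(knees)


def _branch_labels(c: np.ndarray, knees: Sequence[tuple[float, float]]) -> np.ndarray:
    labels = np.full(c.size, "lower", dtype=object)
    if len(knees) >= 2:
        c_lo = min(knees[0][1], knees[1][1])
        c_hi = max(knees[0][1], knees[1][1])
        labels[(c > c_lo) & (c < c_hi)] = "middle"
        labels[c >= c_hi] = "upper"
    elif len(knees) == 1:
        labels[c >= knees[0][1]] = "middle"
    return labels


def c_nullcline(params: ParameterSet, c_grid: np.ndarray | None = None) -> NullclineCurve:
    """Construct the c-nullcline on a grid of circulating-CRH values.

    The default grid spans [0, c_end) where the closed form leaves its
    domain (u -> 1), densely enough to resolve folds near the reference set.
    Inadmissible grid points (u < 0 or u >= 1) are dropped; if nothing is
    admissible an explicit empty curve is returned.
    """
    if c_grid is None:
        c_end = _c_domain_end(params)
        c_grid = np.linspace(0.0, c_end * (1.0 - 1e-9), 2401)[:-1]
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(c_grid < 0):
        raise ValueError("c_grid must be nonnegative")
    cs = c_nullcline_cs_of_c(c_grid, params)
    ok = np.isfinite(cs)
    c_ok, cs_ok = c_grid[ok], cs[ok]
    if c_ok.size == 0:
        return NullclineCurve(which="c_nullcline", c=c_ok, cs=cs_ok)
    knees = _detect_knees(c_ok, cs_ok)
    return NullclineCurve(
        which="c_nullcline", c=c_ok, cs=cs_ok, knees=knees,
        branch_labels=_branch_labels(c_ok, knees),
    )


def cs_nullcline(
    params: ParameterSet,
    c_grid: np.ndarray | None = None,
    step: float = DEFAULT_STEP,
    transient: float | None = None,
    record: float | None = None,
) -> NullclineCurve:
    """Construct the cs-nullcline by period-averaging the PA attractor per c."""
    kwargs = {}
    if transient is not None:
        kwargs["transient"] = transient
    if record is not None:
        kwargs["record"] = record
    if c_grid is None:
        c_end = _c_domain_end(params)
        c_grid = np.linspace(0.02 * c_end, 0.985 * c_end, _DEFAULT_CS_GRID_POINTS)
    c_grid = np.asarray(c_grid, dtype=float)
    cs_vals = np.empty(c_grid.size)
    osc = np.empty(c_grid.size, dtype=bool)
    mean_o = np.empty(c_grid.size)
    for i, cv in enumerate(c_grid):
        summ = characterize(float(cv), params, step=step, **kwargs)
        cs_vals[i] = params.c_inf_bar + summ.mean_exp_bo
        osc[i] = summ.oscillatory
        mean_o[i] = summ.mean_o
    return NullclineCurve(
        which="cs_nullcline", c=c_grid, cs=cs_vals, oscillatory=osc, mean_o=mean_o,
    )


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPoint:
    """An intersection of the projected nullclines with its classification."""

    cs: float
    c: float
    stability: str  # "stable" | "unstable" | "degenerate"
    regime: str     # "normal" | "diseased" | "unstable" | "unclassified"
    mean_o: float
    oscillatory: bool
    period: float | None

    def to_dict(self) -> dict:
        return {
            "cs": self.cs, "c": self.c, "stability": self.stability,
            "regime": self.regime, "mean_o": self.mean_o,
            "oscillatory": self.oscillatory, "period": self.period,
        }


def _relax_endpoint(
    params: ParameterSet,
    start: SystemState,
    horizon: float,
    step: float,
) -> tuple[float, float]:
    """Integrate the full system and return time-smoothed terminal (cs, c)."""
    hist = constant_history(start, t0=0.0, t_d=params.t_d)
    traj = integrate(params, hist, (0.0, horizon), step=step)
    tail = traj.t >= traj.t[-1] - 10.0
    return float(traj.cs[tail].mean()), float(traj.c[tail].mean())


def _classify_stability(
    params: ParameterSet,
    cs0: float,
    c0: float,
    summary: LimitCycleSummary,
    step: float,
    delta: float = 0.01,
    horizon: float | None = None,
) -> str:
    """Stability by direct perturbation of the slow variable.

    The reduced (cs, c) description sits on top of an oscillatory, delayed
    fast subsystem, so a plain Jacobian is ill-defined; instead the full
    system is integrated from small +/- perturbations in cs and the point is
    stable iff both runs return to it.
    """
    if horizon is None:
        horizon = 8.0 * params.t_c
    returned = []
    for sign in (+1.0, -1.0):
        cs_p = max(cs0 + sign * delta, 0.0)
        start = SystemState(
            cs=cs_p, c=c0, a=summary.orbit_a[0], r=summary.orbit_r[0], o=summary.orbit_o[0],
        )
        cs_end, c_end = _relax_endpoint(params, start, horizon, step)
        returned.append(abs(cs_end - cs0) < 0.5 * delta and abs(c_end - c0) < 50 * delta)
    if all(returned):
        return "stable"
    if not any(returned):
        return "unstable"
    return "unstable"  # departs on one side: saddle-like on the slow manifold


def find_fixed_points(
    params: ParameterSet,
    c_curve: NullclineCurve | None = None,
    cs_curve: NullclineCurve | None = None,
    step: float = DEFAULT_STEP,
    classify: bool = True,
    xtol: float = 1e-4,
) -> list[FixedPoint]:
    """Locate and classify the intersections of the two nullclines.

    Both curves are single-valued in c, so intersections are roots of
    ``f(c) = cs_c-nullcline(c) - cs_cs-nullcline(c)``; sign changes on the
    cs-curve grid are refined by Brent's method with the averaged PA target
    re-evaluated exactly at each iterate.  Near-tangential crossings (|f|
    below resolution without a clean sign change) are flagged degenerate.
    """
    if c_curve is None:
        c_curve = c_nullcline(params)
    if cs_curve is None:
        cs_curve = cs_nullcline(params, step=step)
    if c_curve.is_empty or cs_curve.is_empty:
        return []

    c_lo = max(c_curve.c.min(), cs_curve.c.min())
    c_hi = min(c_curve.c.max(), cs_curve.c.max())
    grid = cs_curve.c[(cs_curve.c >= c_lo) & (cs_curve.c <= c_hi)]
    if grid.size < 2:
        return []

    summaries: dict[float, LimitCycleSummary] = {}

    def f(cv: float) -> float:
        cs_c = c_nullcline_cs_of_c(cv, params)
        if not np.isfinite(cs_c):
            return np.nan
        summ = characterize(cv, params, step=step)
        summaries[cv] = summ
        return cs_c - (params.c_inf_bar + summ.mean_exp_bo)

    fvals = np.array([f(cv) for cv in grid])
    pts: list[FixedPoint] = []
    for i in range(grid.size - 1):
        f0, f1 = fvals[i], fvals[i + 1]
        if not (np.isfinite(f0) and np.isfinite(f1)):
            continue
        if f0 == 0.0:
            c_star = float(grid[i])
        elif f0 * f1 < 0:
            c_star = float(brentq(f, grid[i], grid[i + 1], xtol=xtol))
        else:
            continue
        summ = summaries.get(c_star) or characterize(c_star, params, step=step)
        cs_star = float(c_nullcline_cs_of_c(c_star, params))
        stability = (
            _classify_stability(params, cs_star, c_star, summ, step)
            if classify else "unclassified"
        )
        pts.append(FixedPoint(
            cs=cs_star, c=c_star, stability=stability, regime="unclassified",
            mean_o=summ.mean_o, oscillatory=summ.oscillatory, period=summ.period,
        ))

    # regime labels: among stable points the larger cortisol average is the
    # normal state, the smaller the diseased state
    stable = [p for p in pts if p.stability == "stable"]
    regimes: dict[int, str] = {}
    if len(stable) >= 2:
        by_o = sorted(stable, key=lambda p: p.mean_o)
        regimes[id(by_o[0])] = "diseased"
        regimes[id(by_o[-1])] = "normal"
    elif len(stable) == 1:
        regimes[id(stable[0])] = "normal"
    out = []
    for p in pts:
        regime = regimes.get(id(p), "unstable" if p.stability == "unstable" else "unclassified")
        out.append(FixedPoint(
            cs=p.cs, c=p.c, stability=p.stability, regime=regime,
            mean_o=p.mean_o, oscillatory=p.oscillatory, period=p.period,
        ))
    return out


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def curve_summary(curve: NullclineCurve) -> dict:
    """Scalar descriptors of a curve used by the parameter-sweep ledger."""
    d: dict = {
        "which": curve.which,
        "n_samples": int(curve.c.size),
        "folded": curve.folded,
        "knees": list(curve.knees),
    }
    if curve.is_empty:
        return d
    d["c_range"] = (float(curve.c.min()), float(curve.c.max()))
    d["cs_range"] = (float(curve.cs.min()), float(curve.cs.max()))
    if curve.which == "c_nullcline" and curve.folded and len(curve.knees) >= 2:
        ks = sorted(curve.knees, key=lambda kc: kc[1])  # by c
        d["upper_knee_cs"], d["upper_knee_c"] = ks[0]
        d["lower_knee_cs"], d["lower_knee_c"] = ks[1]
        d["bistable_cs_window"] = (min(ks[0][0], ks[1][0]), max(ks[0][0], ks[1][0]))
    if curve.oscillatory is not None:
        rng = curve.oscillatory_c_range()
        d["oscillatory_c_range"] = rng
        if rng is not None:
            mask = curve.oscillatory
            d["oscillatory_c_extent"] = rng[1] - rng[0]
            d["oscillatory_cs_mean"] = float(curve.cs[mask].mean())
    return d


def sweep(
    params: ParameterSet,
    target: str,
    values: Sequence[float],
    curve: str = "c",
    **curve_kwargs,
) -> tuple[list[NullclineCurve], list[dict]]:
    """One-parameter family of nullclines plus per-value curve summaries.

    ``curve`` selects which nullcline to recompute ("c" or "cs").  Returns
    the curves (one per value) and matching summaries with knee positions,
    branch extents and oscillatory ranges for qualitative-shift checks.
    """
    if target not in ParameterSet.names():
        raise ValueError(
            f"unknown parameter {target!r}; valid names: {ParameterSet.names()}"
        )
    if curve not in ("c", "cs"):
        raise ValueError("curve must be 'c' or 'cs'")
    curves: list[NullclineCurve] = []
    summaries: list[dict] = []
    for v in values:
        if v <= 0:
            raise ValueError("swept parameter values must be positive")
        p = params.replace(**{target: float(v)})
        crv = c_nullcline(p, **curve_kwargs) if curve == "c" else cs_nullcline(p, **curve_kwargs)
        curves.append(crv)
        s = curve_summary(crv)
        s[target] = float(v)
        summaries.append(s)
    return curves, summaries
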