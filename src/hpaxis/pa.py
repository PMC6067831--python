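"""Pituitary-adrenal (PA) subsystem analysis at fixed circulating CRH.

With ``c`` clamped, the (a, r, o) subsystem with adrenal delay ``t_d`` has a
single attractor for the parameter ranges of interest: a fixed point at low
drive and, past a delay-induced Hopf onset, an ultradian limit cycle whose
amplitude and period depend continuously on ``c``.  This module detects the
attractor, parameterizes the orbit by phase (theta = 0 at the cortisol
maximum), and computes the cycle averages that the slow stored-CRH equation
feels -- in particular the averaged synthesis target
``<c_inf(c)> = c_inf_bar + <exp(-b o)>`` used by the cs-nullcline.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .model import SystemState
from .parameters import ParameterSet
from .solver import DEFAULT_STEP, constant_history, integrate, Trajectory

__all__ = [
    "LimitCycleSummary",
    "UnresolvedAttractorError",
    "characterize",
    "averaged_crh_target",
    "oscillatory_c_range",
]

#: Burn-in long enough for transients of the delayed PA loop to die out.
DEFAULT_TRANSIENT = 300.0
#: Recording window (tens of ultradian cycles at the reference delay).
DEFAULT_RECORD = 120.0
#: Relative peak-to-trough amplitude below which the attractor is a fixed point.
DEFAULT_TOL = 1e-6

_N_PHASE = 256


class UnresolvedAttractorError(RuntimeError):
    """The PA subsystem neither settled on a fixed point nor closed a cycle."""

    def __init__(self, c: float, message: str):
        super().__init__(f"c={c}: {message}")
        self.c = c


@dataclass(frozen=True)
class LimitCycleSummary:
    """Attractor of the PA subsystem at one clamped CRH level.

    ``theta`` runs over [0, 2pi) with theta = 0 anchored at the cortisol
    maximum; ``orbit_*`` are the phase-parameterized samples.  For a fixed
    point the orbit is constant and every mean equals the point value.
    """

    c: float
    oscillatory: bool
    period: float | None
    theta: np.ndarray
    orbit_o: np.ndarray
    orbit_a: np.ndarray
    orbit_r: np.ndarray
    mean_o: float
    mean_a: float
    mean_r: float
    mean_or: float
    mean_exp_bo: float
    amplitude: float

    def to_json(self) -> str:
        d = {
            "c": self.c,
            "oscillatory": self.oscillatory,
            "period": self.period,
            "theta": self.theta.tolist(),
            "orbit_o": self.orbit_o.tolist(),
            "orbit_a": self.orbit_a.tolist(),
            "orbit_r": self.orbit_r.tolist(),
            "mean_o": self.mean_o,
            "mean_a": self.mean_a,
            "mean_r": self.mean_r,
            "mean_or": self.mean_or,
            "mean_exp_bo": self.mean_exp_bo,
            "amplitude": self.amplitude,
        }
        return json.dumps(d)

    @property
    def fixed_point(self) -> SystemState | None:
        if self.oscillatory:
            return None
        return SystemState(cs=0.0, c=self.c, a=self.mean_a, r=self.mean_r, o=self.mean_o)


def _refine_peak(t: np.ndarray, o: np.ndarray, i: int) -> float:
    """Vertex of the parabola through three nodes around a discrete maximum."""
    if i <= 0 or i >= o.size - 1:
        return float(t[i])
    y0, y1, y2 = o[i - 1], o[i], o[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(t[i] + delta * (t[i + 1] - t[i]))


def characterize(
    c: float,
    params: ParameterSet,
    transient: float = DEFAULT_TRANSIENT,
    record: float = DEFAULT_RECORD,
    tol: float = DEFAULT_TOL,
    step: float = DEFAULT_STEP,
    initial: SystemState | None = None,
    n_phase: int = _N_PHASE,
) -> LimitCycleSummary:
    """Integrate the clamped PA subsystem and summarize its attractor.

    Periodicity is detected from successive upward crossings of cortisol
    through its window mean (a Poincare-style section); the attractor is
    declared a fixed point when the relative peak-to-trough amplitude over
    the recording tail falls below ``tol``.  Near the Hopf onset transients
    decay slowly, so on a failed detection the burn-in is doubled (twice)
    before an :class:`UnresolvedAttractorError` is raised.  ``n_phase``
    controls the phase resolution of the sampled orbit (and with it the
    quadrature of the cycle averages).
    """
    if c < 0:
        raise ValueError("clamped CRH level c must be nonnegative")
    last_err: UnresolvedAttractorError | None = None
    for factor in (1.0, 2.0, 4.0):
        try:
            return _characterize_once(
                c, params, factor * transient, record, tol, step, initial, n_phase,
            )
        except UnresolvedAttractorError as err:
            last_err = err
    raise last_err


def _characterize_once(
    c: float,
    params: ParameterSet,
    transient: float,
    record: float,
    tol: float,
    step: float,
    initial: SystemState | None,
    n_phase: int = _N_PHASE,
) -> LimitCycleSummary:
    if initial is None:
        initial = SystemState(cs=1.0, c=c, a=0.1, r=0.2, o=0.1)
    else:
        initial = SystemState(cs=initial.cs, c=c, a=initial.a, r=initial.r, o=initial.o)
    hist = constant_history(initial, t0=0.0, t_d=params.t_d)
    traj = integrate(params, hist, (0.0, transient + record), step=step, clamp_cs_c=True)

    sel = traj.t >= transient
    ts = traj.t[sel]
    o = traj.o[sel]
    a = traj.a[sel]
    r = traj.r[sel]

    tail = ts >= ts[0] + 0.5 * (ts[-1] - ts[0])
    o_tail = o[tail]
    amp_tail = float(o_tail.max() - o_tail.min())
    scale = max(1.0, abs(float(o_tail.mean())))

    if amp_tail < tol * scale:
        # fixed point; also require the trajectory to have stopped drifting
        drift = abs(float(o[-1]) - float(o[o.size // 2]))
        if drift > 100 * tol * scale:
            raise UnresolvedAttractorError(c, "amplitude below tolerance but still drifting")
        o_fp, a_fp, r_fp = float(o[-1]), float(a[-1]), float(r[-1])
        theta = np.linspace(0.0, 2.0 * np.pi, n_phase, endpoint=False)
        const = np.full(n_phase, o_fp)
        return LimitCycleSummary(
            c=float(c), oscillatory=False, period=None, theta=theta,
            orbit_o=const, orbit_a=np.full(n_phase, a_fp), orbit_r=np.full(n_phase, r_fp),
            mean_o=o_fp, mean_a=a_fp, mean_r=r_fp, mean_or=o_fp * r_fp,
            mean_exp_bo=float(np.exp(-params.b * o_fp)), amplitude=amp_tail,
        )

    m = float(o.mean())
    up = np.nonzero((o[:-1] < m) & (o[1:] >= m))[0]
    if up.size < 4:
        raise UnresolvedAttractorError(c, "no cycle closure within the recording window")
    # linearly refined crossing times
    t_cross = ts[up] + (m - o[up]) / (o[up + 1] - o[up]) * (ts[up + 1] - ts[up])
    intervals = np.diff(t_cross)
    use = intervals[-min(10, intervals.size):]
    period = float(use.mean())
    if float(use.std()) > 5e-3 * period:
        raise UnresolvedAttractorError(c, "cycle period did not converge")

    # anchor theta = 0 at the cortisol maximum of the last complete cycle
    t_lo = t_cross[-2]
    win = (ts >= t_lo - period) & (ts <= t_lo + period)
    i_win = np.nonzero(win)[0]
    i_pk = i_win[np.argmax(o[i_win])]
    t_peak = _refine_peak(ts, o, i_pk)
    if t_peak + period > ts[-1]:
        t_peak -= period

    theta = np.linspace(0.0, 2.0 * np.pi, n_phase, endpoint=False)
    t_phase = t_peak + theta / (2.0 * np.pi) * period
    orbit_o = traj.values_at(t_phase, "o")
    orbit_a = traj.values_at(t_phase, "a")
    orbit_r = traj.values_at(t_phase, "r")
    # uniform phase sampling of a periodic orbit: plain means are the cycle averages
    mean_o = float(orbit_o.mean())
    mean_a = float(orbit_a.mean())
    mean_r = float(orbit_r.mean())
    mean_or = float((orbit_o * orbit_r).mean())
    mean_exp_bo = float(np.exp(-params.b * orbit_o).mean())
    return LimitCycleSummary(
        c=float(c), oscillatory=True, period=period, theta=theta,
        orbit_o=orbit_o, orbit_a=orbit_a, orbit_r=orbit_r,
        mean_o=mean_o, mean_a=mean_a, mean_r=mean_r, mean_or=mean_or,
        mean_exp_bo=mean_exp_bo, amplitude=float(orbit_o.max() - orbit_o.min()),
    )


def averaged_crh_target(
    c: float,
    params: ParameterSet,
    summary: LimitCycleSummary | None = None,
    **characterize_kwargs,
) -> float:
    """Cycle-averaged stored-CRH synthesis target ``<c_inf(c)>``.

    Equals ``c_inf_bar + <exp(-b o)>`` with the average taken over the PA
    attractor at clamped CRH level ``c`` (a point value if non-oscillatory).
    """
    if summary is None:
        summary = characterize(c, params, **characterize_kwargs)
    return params.c_inf_bar + summary.mean_exp_bo


def _is_oscillatory(c: float, params: ParameterSet, **kwargs) -> bool:
    try:
        return characterize(c, params, **kwargs).oscillatory
    except UnresolvedAttractorError:
        # a cycle that never settles cleanly is still not a fixed point
        return True


def oscillatory_c_range(
    params: ParameterSet,
    c_lo: float = 2.0,
    c_hi: float = 120.0,
    c_mid: float = 25.0,
    tol_c: float = 0.05,
    **characterize_kwargs,
) -> tuple[float, float]:
    """Bisect the onset and offset of the PA limit cycle along c.

    Assumes the subsystem oscillates at ``c_mid`` and is quiescent at both
    ``c_lo`` and ``c_hi`` (the delay-induced instability occupies an
    interior window of drive levels); raises if the assumption fails.
    """
    if not _is_oscillatory(c_mid, params, **characterize_kwargs):
        raise ValueError(f"PA subsystem is not oscillatory at c_mid={c_mid}")
    if _is_oscillatory(c_lo, params, **characterize_kwargs):
        raise ValueError(f"oscillation extends below c_lo={c_lo}")
    if _is_oscillatory(c_hi, params, **characterize_kwargs):
        raise ValueError(f"oscillation extends above c_hi={c_hi}")
    a, b = c_lo, c_mid
    while b - a > tol_c:
        m = 0.5 * (a + b)
        if _is_oscillatory(m, params, **characterize_kwargs):
            b = m
        else:
            a = m
    onset = 0.5 * (a + b)
    a, b = c_mid, c_hi
    while b - a > tol_c:
        m = 0.5 * (a + b)
        if _is_oscillatory(m, params, **characterize_kwargs):
            a = m
        else:
            b = m
    return onset, 0.5 * (a + b)
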