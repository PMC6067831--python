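"""Independent reference integrators used only as test oracles.

These deliberately share no code with the package solver: the clamped
pituitary-adrenal subsystem is integrated by the method of steps with
scipy's adaptive RK45 and its dense output as the delayed-term history,
so agreement with the package's fixed-step RK4 + Hermite machinery is a
genuine dual-route check.
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def integrate_pa_reference(c, params, t_end, y0=(0.1, 0.2, 0.1), rtol=1e-10, atol=1e-12):
    """Clamped PA subsystem (a, r, o) from a constant history, adaptive RK45.

    Returns a callable ``sol(t) -> (a, r, o)`` valid on [0, t_end].
    """
    td = params.t_d
    p2, p3, p4, p5, p6 = params.p2, params.p3, params.p4, params.p5, params.p6
    a0 = y0[0]

    segments = []  # list of (t_lo, t_hi, dense solution)

    def a_delayed(t):
        ts = t - td
        if ts <= 0.0:
            return a0
        for lo, hi, dense in segments:
            if lo - 1e-9 <= ts <= hi + 1e-9:
                return dense(min(max(ts, lo), hi))[0]
        raise RuntimeError(f"delayed time {ts} not covered")

    def rhs(t, y):
        a, r, o = y
        orp = o * r
        fa = 1.0 / (1.0 + p2 * orp)
        gr = orp * orp / (p4 + orp * orp) + p5
        return [c * fa - p3 * a, gr - p6 * r, a_delayed(t) - o]

    t = 0.0
    y = np.asarray(y0, dtype=float)
    while t < t_end - 1e-12:
        t_next = min(t + td, t_end)
        sol = solve_ivp(rhs, (t, t_next), y, method="RK45", dense_output=True,
                        rtol=rtol, atol=atol, max_step=td / 4)
        if not sol.success:
            raise RuntimeError(sol.message)
        segments.append((t, t_next, sol.sol))
        t, y = t_next, sol.y[:, -1]

    def evaluate(tq):
        tq = float(tq)
        for lo, hi, dense in segments:
            if lo <= tq <= hi:
                return dense(tq)
        raise ValueError(f"time {tq} outside [0, {t_end}]")

    return evaluate


def exact_pk_level(t, height, width, decay):
    """Closed-form one-compartment drug level for a rectangle infusion at t=0."""
    t = np.asarray(t, dtype=float)
    rise = (height / decay) * (1.0 - np.exp(-decay * np.clip(t, 0.0, width)))
    tail = np.where(t > width, np.exp(-decay * (t - width)), 1.0)
    level = np.where(t <= 0, 0.0, np.where(t <= width, rise,
                     (height / decay) * (1.0 - np.exp(-decay * width)) * tail))
    return level
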