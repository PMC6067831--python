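"""Compiled inner loops for the delay-differential integrator.

Method of steps with classical fixed-step RK4.  The delayed terms
``a(t - t_d)`` and ``a_exo(t - t_d)`` are read from the stored solution via
cubic Hermite interpolation (node values + node derivatives), which keeps
the interpolant locally O(h^4) and the overall scheme fourth order.

Node derivatives are stored two-sided: the right-hand side is discontinuous
at segment boundaries (history junction, rectangle-input edges), so the
derivative at a node as the *left* end of the following interval
(``dl_arr``) can differ from the derivative as the *right* end of the
preceding interval (``dr_arr``).  Interval [i, i+1] interpolates with
``dl_arr[i]`` and ``dr_arr[i+1]``.

Parameter packing order (must match ``ParameterSet`` field order):
q0, q1, q2, gc_max, n, k, b, c_inf_bar, t_c, p2, p3, p4, p5, p6, t_d, I0, p7, p8.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# indices into the packed parameter vector
_Q0, _Q1, _Q2, _GCMAX, _N, _K, _B, _CBAR, _TC = 0, 1, 2, 3, 4, 5, 6, 7, 8
_P2, _P3, _P4, _P5, _P6, _TD, _I0, _P7, _P8 = 9, 10, 11, 12, 13, 14, 15, 16, 17

# column indices of the state vector
COL_CS, COL_C, COL_A, COL_R, COL_O, COL_OEXO, COL_AEXO = 0, 1, 2, 3, 4, 5, 6


@njit(cache=False)
def _rhs7(y, a_del, aexo_del, I, pi_o, pi_a, P, clamp_cs_c):
    """Derivatives of (cs, c, a, r, o, o_exo, a_exo).

    ``clamp_cs_c`` freezes the two hypothalamic variables (used to study the
    pituitary-adrenal subsystem at fixed circulating CRH).
    """
    cs = y[0]; c = y[1]; a = y[2]; r = y[3]; o = y[4]
    oexo = y[5]; aexo = y[6]
    dy = np.empty(7)
    if clamp_cs_c:
        dy[0] = 0.0
        dy[1] = 0.0
    else:
        dy[0] = (P[_CBAR] + np.exp(-P[_B] * o) - cs) / P[_TC]
        x = (P[_Q1] * c) ** P[_N]
        dy[1] = (P[_Q0] * I * (1.0 - np.exp(-P[_K] * cs))
                 + P[_GCMAX] * x / (1.0 + x) - P[_Q2] * c)
    ore = (o + oexo) * r
    dy[2] = c / (1.0 + P[_P2] * ore) - P[_P3] * a
    dy[3] = ore * ore / (P[_P4] + ore * ore) + P[_P5] - P[_P6] * r
    dy[4] = a_del + aexo_del - o
    dy[5] = pi_o - P[_P7] * oexo
    dy[6] = pi_a - P[_P8] * aexo
    return dy


@njit(cache=False)
def _hermite_col(t_arr, y_arr, dl_arr, dr_arr, i_last, ts, col):
    """Cubic Hermite evaluation of stored column ``col`` at time ``ts``.

    ``ts`` must lie within [t_arr[0], t_arr[i_last]]; values marginally
    outside (floating-point slack) clamp to the boundary nodes.
    """
    if ts <= t_arr[0]:
        return y_arr[0, col]
    if ts >= t_arr[i_last]:
        return y_arr[i_last, col]
    lo = 0
    hi = i_last
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if t_arr[mid] <= ts:
            lo = mid
        else:
            hi = mid
    tl = t_arr[lo]
    dt = t_arr[lo + 1] - tl
    s = (ts - tl) / dt
    s2 = s * s
    s3 = s2 * s
    h00 = 2.0 * s3 - 3.0 * s2 + 1.0
    h10 = s3 - 2.0 * s2 + s
    h01 = -2.0 * s3 + 3.0 * s2
    h11 = s3 - s2
    return (h00 * y_arr[lo, col] + h10 * dt * dl_arr[lo, col]
            + h01 * y_arr[lo + 1, col] + h11 * dt * dr_arr[lo + 1, col])


@njit(cache=False)
def _delayed_pair(t_arr, y_arr, dl_arr, dr_arr, i_last, ts):
    a_del = _hermite_col(t_arr, y_arr, dl_arr, dr_arr, i_last, ts, COL_A)
    x_del = _hermite_col(t_arr, y_arr, dl_arr, dr_arr, i_last, ts, COL_AEXO)
    return a_del, x_del


@njit(cache=False)
def _integrate_segment(t_arr, y_arr, dl_arr, dr_arr, i0, t_end, h, P,
                       I, pi_o, pi_a, clamp_cs_c):
    """Advance the solution from node ``i0`` to ``t_end`` under constant inputs.

    Returns the index of the last node written, or ``-(i+1)`` on a
    nonfinite/blow-up failure at node ``i``.
    """
    td = P[_TD]
    i = i0
    t_start = t_arr[i0]
    # forward derivative at segment entry under this segment's inputs; the
    # right-sided derivative dr_arr[i0] (previous segment / history) is kept
    if td > 0.0:
        a_del, x_del = _delayed_pair(t_arr, y_arr, dl_arr, dr_arr, i, t_start - td)
    else:
        a_del = y_arr[i, COL_A]
        x_del = y_arr[i, COL_AEXO]
    dl_arr[i] = _rhs7(y_arr[i], a_del, x_del, I, pi_o, pi_a, P, clamp_cs_c)

    span = t_end - t_start
    n_full = int(np.floor(span / h + 1e-9))
    remainder = span - n_full * h
    n_steps = n_full + (1 if remainder > 1e-9 else 0)

    for m in range(n_steps):
        t = t_arr[i]
        hstep = h if m < n_full else remainder
        t_next = t_start + (m + 1) * h if m < n_full else t_end

        y0 = y_arr[i]
        k1 = dl_arr[i]
        tm = t + 0.5 * hstep
        a_m = 0.0; x_m = 0.0; a_e = 0.0; x_e = 0.0
        if td > 0.0:
            a_m, x_m = _delayed_pair(t_arr, y_arr, dl_arr, dr_arr, i, tm - td)
            a_e, x_e = _delayed_pair(t_arr, y_arr, dl_arr, dr_arr, i, t_next - td)

        y1 = y0 + 0.5 * hstep * k1
        if td == 0.0:
            a_m = y1[COL_A]; x_m = y1[COL_AEXO]
        k2 = _rhs7(y1, a_m, x_m, I, pi_o, pi_a, P, clamp_cs_c)
        y2 = y0 + 0.5 * hstep * k2
        if td == 0.0:
            a_m = y2[COL_A]; x_m = y2[COL_AEXO]
        k3 = _rhs7(y2, a_m, x_m, I, pi_o, pi_a, P, clamp_cs_c)
        y3 = y0 + hstep * k3
        if td == 0.0:
            a_e = y3[COL_A]; x_e = y3[COL_AEXO]
        k4 = _rhs7(y3, a_e, x_e, I, pi_o, pi_a, P, clamp_cs_c)

        ynew = y0 + (hstep / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        ok = True
        for j in range(7):
            v = ynew[j]
            if not np.isfinite(v):
                ok = False
                break
            if v < 0.0:
                # RK4 can undershoot an invariant boundary by O(h^5); clamp
                # numerical dust, fail on a genuine excursion
                if v > -1e-9:
                    ynew[j] = 0.0
                else:
                    ok = False
                    break
        i += 1
        t_arr[i] = t_next
        y_arr[i] = ynew
        if not ok:
            return -i
        if td > 0.0:
            a_del, x_del = _delayed_pair(t_arr, y_arr, dl_arr, dr_arr, i, t_next - td)
        else:
            a_del = ynew[COL_A]
            x_del = ynew[COL_AEXO]
        dnew = _rhs7(ynew, a_del, x_del, I, pi_o, pi_a, P, clamp_cs_c)
        dr_arr[i] = dnew
        dl_arr[i] = dnew  # overwritten at entry if the next segment differs
    return i
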