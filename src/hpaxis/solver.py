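"""Delay-differential integrator: method of steps with fixed-step RK4.

The integrator restarts exactly at every rectangle-input boundary (dose
pulses and stressor steps), so the piecewise-constant forcing is never
straddled by a step and the solution remains fourth-order accurate on every
smooth segment.  The dense output used for the delayed terms is the cubic
Hermite interpolant of the stored nodes.  There is no randomness anywhere:
runs are bit-reproducible from their configuration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._kernels import _hermite_col, _integrate_segment
from .model import STATE_NAMES, DosePulse, InputSignal, SystemState
from .parameters import ParameterSet

__all__ = [
    "HistoryFunction",
    "Trajectory",
    "IntegrationError",
    "constant_history",
    "integrate",
    "DEFAULT_STEP",
]

#: Default integration step in dimensionless time (~6 s of real time).
DEFAULT_STEP = 0.01


class IntegrationError(RuntimeError):
    """Raised when the integration produces a nonfinite or negative state."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


def _pack(params: ParameterSet) -> np.ndarray:
    return np.array([getattr(params, name) for name in ParameterSet.names()], dtype=float)


@dataclass(frozen=True)
class HistoryFunction:
    """Dense state history on a lookback window, with node derivatives.

    Evaluation between nodes uses the same cubic Hermite rule as the solver,
    so continuing a run from a stored tail reproduces the unsplit run.
    ``derivs`` holds the right-sided node derivatives, ``derivs_left`` the
    left-sided ones; they differ only at input discontinuities (pulse edges)
    inherited from a previous run.
    """

    times: np.ndarray
    states: np.ndarray  # (m, 7)
    derivs: np.ndarray  # (m, 7)
    derivs_left: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        dy = np.asarray(self.derivs, dtype=float)
        dl = dy if self.derivs_left is None else np.asarray(self.derivs_left, dtype=float)
        if t.ndim != 1 or y.shape != (t.size, 7) or dy.shape != (t.size, 7):
            raise ValueError("history arrays must be (m,), (m,7), (m,7)")
        if dl.shape != dy.shape:
            raise ValueError("derivs_left must match derivs in shape")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("history times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("history states must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)
        object.__setattr__(self, "derivs", dy)
        object.__setattr__(self, "derivs_left", dl)

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def __call__(self, t: float) -> SystemState:
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise ValueError(f"history evaluated outside its window at t={t}")
        t = min(max(t, self.times[0]), self.times[-1])
        y = np.array([
            _hermite_col(self.times, self.states, self.derivs_left, self.derivs,
                         self.times.size - 1, t, col)
            for col in range(7)
        ])
        return SystemState.from_array(np.maximum(y, 0.0))


def constant_history(state: SystemState, t0: float = 0.0, t_d: float = 1.44) -> HistoryFunction:
    """History equal to ``state`` on the lookback window ``[t0 - t_d, t0]``."""
    if t_d < 0:
        raise ValueError("t_d must be nonnegative")
    y = state.as_array()
    if t_d == 0.0:
        times = np.array([t0])
        states = y[None, :]
    else:
        times = np.array([t0 - t_d, t0])
        states = np.vstack([y, y])
    return HistoryFunction(times, states, np.zeros_like(states))


@dataclass(frozen=True)
class Trajectory:
    """An integrated solution on a node grid, plus the realized inputs.

    Nodes before ``t_start`` are the history prefix kept for delayed lookups
    and continuation; public accessors expose the run proper (t >= t_start).
    """

    times: np.ndarray
    states: np.ndarray  # (N, 7)
    derivs: np.ndarray  # (N, 7) right-sided node derivatives
    t_start: float
    params: ParameterSet
    derivs_left: np.ndarray = None  # left-sided (differs at input edges)
    input_I: np.ndarray = None
    input_pi_dex: np.ndarray = None
    input_pi_acth: np.ndarray = None

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.derivs_left is None:
            object.__setattr__(self, "derivs_left", self.derivs)

    # -- accessors ---------------------------------------------------------
    @property
    def run_slice(self) -> slice:
        i0 = int(np.searchsorted(self.times, self.t_start - 1e-12))
        return slice(i0, self.times.size)

    @property
    def t(self) -> np.ndarray:
        return self.times[self.run_slice]

    def __getattr__(self, name: str):
        if name in STATE_NAMES:
            return self.states[self.run_slice, STATE_NAMES.index(name)]
        raise AttributeError(name)

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def state_at(self, t: float) -> SystemState:
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise ValueError(f"time {t} outside trajectory range")
        t = min(max(t, self.times[0]), self.times[-1])
        y = np.array([
            _hermite_col(self.times, self.states, self.derivs_left, self.derivs,
                         self.times.size - 1, t, col)
            for col in range(7)
        ])
        return SystemState.from_array(np.maximum(y, 0.0))

    def values_at(self, ts: np.ndarray, name: str) -> np.ndarray:
        """Dense evaluation of one component on arbitrary times inside the range."""
        col = STATE_NAMES.index(name)
        return np.array([
            _hermite_col(self.times, self.states, self.derivs_left, self.derivs,
                         self.times.size - 1, float(t), col)
            for t in np.asarray(ts, dtype=float)
        ])

    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[-1])

    def tail_history(self, t_d: float | None = None) -> HistoryFunction:
        """History covering the final lookback window, for continuation runs."""
        t_d = self.params.t_d if t_d is None else t_d
        if t_d == 0.0:
            return HistoryFunction(self.times[-1:], self.states[-1:], self.derivs[-1:],
                                   self.derivs_left[-1:])
        t_lo = self.times[-1] - t_d
        if t_lo < self.times[0] - 1e-9:
            raise ValueError("trajectory shorter than the delay window")
        i0 = max(int(np.searchsorted(self.times, t_lo, side="right")) - 1, 0)
        return HistoryFunction(self.times[i0:], self.states[i0:], self.derivs[i0:],
                               self.derivs_left[i0:])

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        sl = self.run_slice
        data = {"time": self.times[sl]}
        for j, name in enumerate(STATE_NAMES):
            data[name] = self.states[sl, j]
        data["I"] = self.input_I[sl]
        data["pi_dex"] = self.input_pi_dex[sl]
        data["pi_acth"] = self.input_pi_acth[sl]
        return pd.DataFrame(data)

    def config_fingerprint(self) -> str:
        items = ",".join(f"{k}={v:.12g}" for k, v in self.params.to_dict().items())
        return f"# hpaxis trajectory; params: {items}"

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write(self.config_fingerprint() + "\n")
            frame.to_csv(fh, index=False, float_format="%.12g")

    @staticmethod
    def read_csv(path) -> pd.DataFrame:
        """Read a trajectory CSV back into a DataFrame (fingerprint skipped)."""
        return pd.read_csv(path, comment="#")


def _segment_boundaries(
    t0: float, t1: float, input_signal: InputSignal, pulses: Sequence[DosePulse]
) -> list[float]:
    pts = set()
    for p in input_signal.breakpoints():
        if t0 < p < t1:
            pts.add(float(p))
    for pulse in pulses:
        for p in pulse.breakpoints():
            if t0 < p < t1:
                pts.add(float(p))
    return [t0] + sorted(pts) + [t1]


def integrate(
    params: ParameterSet,
    history: HistoryFunction,
    t_span: tuple[float, float],
    input_signal: InputSignal | None = None,
    pulses: Sequence[DosePulse] = (),
    step: float = DEFAULT_STEP,
    clamp_cs_c: bool = False,
) -> Trajectory:
    """Integrate the delayed system over ``t_span`` from an initial history.

    Parameters
    ----------
    params : ParameterSet
        Model constants; ``params.t_d`` is the adrenal delay.
    history : HistoryFunction
        Must cover ``[t0 - t_d, t0]`` and end exactly at ``t0``.
    t_span : (t0, t1)
        Integration window, dimensionless time.
    input_signal : InputSignal, optional
        Synaptic drive; defaults to constant ``params.I0``.
    pulses : sequence of DosePulse
        Rectangle drug infusions into the exogenous compartments.
    step : float
        Fixed RK4 step; must satisfy ``step <= t_d`` when ``t_d > 0`` so a
        delayed lookup never outruns the stored solution.
    clamp_cs_c : bool
        Freeze ``cs`` and ``c`` (pituitary-adrenal subsystem analysis).
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not (math.isfinite(t0) and math.isfinite(t1)) or t1 <= t0:
        raise ValueError("t_span must be finite with t1 > t0")
    if step <= 0:
        raise ValueError("step must be strictly positive")
    td = params.t_d
    if td > 0 and step > td + 1e-12:
        raise ValueError(f"step ({step}) must not exceed the delay t_d ({td})")
    if abs(history.t_end - t0) > 1e-9:
        raise ValueError("history must end exactly at t_span[0]")
    if td > 0 and history.t_start > t0 - td + 1e-9:
        raise ValueError("history does not cover the full lookback window [t0 - t_d, t0]")
    if input_signal is None:
        input_signal = InputSignal(baseline=params.I0)

    bounds = _segment_boundaries(t0, t1, input_signal, pulses)
    n_hist = history.times.size
    n_nodes = n_hist + sum(
        int(math.floor((b1 - b0) / step + 1e-9)) + 1 for b0, b1 in zip(bounds, bounds[1:])
    ) + 8
    t_arr = np.empty(n_nodes)
    y_arr = np.empty((n_nodes, 7))
    dl_arr = np.empty((n_nodes, 7))
    dr_arr = np.empty((n_nodes, 7))
    t_arr[:n_hist] = history.times
    y_arr[:n_hist] = history.states
    dl_arr[:n_hist] = history.derivs_left
    dr_arr[:n_hist] = history.derivs

    P = _pack(params)
    i = n_hist - 1
    for b0, b1 in zip(bounds, bounds[1:]):
        mid = 0.5 * (b0 + b1)
        I_val = input_signal.value(mid)
        pi_dex = sum(p.rate(mid) for p in pulses if p.compartment == "dex")
        pi_acth = sum(p.rate(mid) for p in pulses if p.compartment == "acth")
        i = _integrate_segment(
            t_arr, y_arr, dl_arr, dr_arr, i, b1, step, P, I_val, pi_dex, pi_acth,
            1 if clamp_cs_c else 0,
        )
        if i < 0:
            t_fail = t_arr[-i]
            raise IntegrationError(
                f"integration failed (nonfinite or negative state) at t={t_fail:.6g}",
                t_fail=float(t_fail),
            )

    times = t_arr[: i + 1].copy()
    states = y_arr[: i + 1].copy()
    derivs = dr_arr[: i + 1].copy()
    derivs_left = dl_arr[: i + 1].copy()
    input_I = np.array([input_signal.value(t) for t in times])
    input_pi_dex = np.array([sum(p.rate(t) for p in pulses if p.compartment == "dex")
                             for t in times])
    input_pi_acth = np.array([sum(p.rate(t) for p in pulses if p.compartment == "acth")
                              for t in times])
    return Trajectory(
        times=times, states=states, derivs=derivs, derivs_left=derivs_left,
        t_start=t0, params=params,
        input_I=input_I, input_pi_dex=input_pi_dex, input_pi_acth=input_pi_acth,
    )
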