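"""State containers, regulatory functions, and the model right-hand side.

Five endogenous state variables: stored CRH ``cs`` at the PVN axon
terminals, circulating CRH ``c``, circulating ACTH ``a``, free pituitary
glucocorticoid receptor ``r``, and circulating cortisol ``o``.  Two optional
exogenous compartments carry administered drugs: ``o_exo`` (dexamethasone in
cortisol equivalents) and ``a_exo`` (cosyntropin in ACTH equivalents).

The cortisol-receptor complex is taken at quasi-steady state and enters the
pituitary equations only through the product ``o*r`` (with ``o`` replaced by
``o + o_exo`` when dexamethasone is present; dexamethasone does not reach
the hypothalamic synthesis equation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "SystemState",
    "InputSignal",
    "DosePulse",
    "STATE_NAMES",
    "release_fraction",
    "autocrine_upregulation",
    "pituitary_feedback",
    "gr_production",
    "crh_synthesis_target",
    "system_rhs",
    "pharmacokinetics_rhs",
]

STATE_NAMES = ("cs", "c", "a", "r", "o", "o_exo", "a_exo")


# ---------------------------------------------------------------------------
# regulatory functions
# ---------------------------------------------------------------------------

def release_fraction(cs: float, k: float) -> float:
    """Fraction of the maximal CRH release rate realized at stored level ``cs``.

    ``h(cs) = 1 - exp(-k*cs)``: saturating, strictly increasing, in [0, 1).
    """
    if k <= 0:
        raise ValueError("k must be strictly positive")
    cs_arr = np.asarray(cs, dtype=float)
    if np.any(cs_arr < 0):
        raise ValueError("stored CRH cs must be nonnegative")
    out = -np.expm1(-k * cs_arr)
    return float(out) if out.ndim == 0 else out


def autocrine_upregulation(c: float, params: ParameterSet) -> float:
    """Auto/paracrine CRH self-upregulation term ``gc(c)``.

    Hill function ``gc_max * (q1*c)^n / (1 + (q1*c)^n)``: zero at c = 0,
    half-maximal at c = 1/q1, saturating at ``gc_max``.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("circulating CRH c must be nonnegative")
    x = (params.q1 * c_arr) ** params.n
    out = params.gc_max * x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def pituitary_feedback(or_product: float, p2: float) -> float:
    """Cortisol negative-feedback factor on ACTH secretion, ``fa(or)``.

    ``1 / (1 + p2*(or))``: equals 1 with no complex, decreasing and convex
    in the complex level.  Convexity is what makes an identical increment of
    cortisol bite harder in a low-(or) state than in a high-(or) state.
    """
    orp = np.asarray(or_product, dtype=float)
    if np.any(orp < 0):
        raise ValueError("complex level or_product must be nonnegative")
    out = 1.0 / (1.0 + p2 * orp)
    return float(out) if out.ndim == 0 else out


def gr_production(or_product: float, p4: float, p5: float) -> float:
    """Glucocorticoid-receptor synthesis rate ``gr(or)``.

    ``(or)^2 / (p4 + (or)^2) + p5``: basal rate p5, cooperative
    self-upregulation saturating at ``1 + p5``.
    """
    orp = np.asarray(or_product, dtype=float)
    if np.any(orp < 0):
        raise ValueError("complex level or_product must be nonnegative")
    x2 = orp * orp
    out = x2 / (p4 + x2) + p5
    return float(out) if out.ndim == 0 else out


def crh_synthesis_target(o: float, b: float, c_inf_bar: float) -> float:
    """Cortisol-set target ``c_inf(o) = c_inf_bar + exp(-b*o)`` for stored CRH.

    Strictly decreasing in cortisol: range ``(c_inf_bar, c_inf_bar + 1]``.
    This is where cortisol's genomic suppression of CRH synthesis enters.
    """
    o_arr = np.asarray(o, dtype=float)
    if np.any(o_arr < 0):
        raise ValueError("cortisol o must be nonnegative")
    out = c_inf_bar + np.exp(-b * o_arr)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemState:
    """A point value of the model state (all components nonnegative)."""

    cs: float
    c: float
    a: float
    r: float
    o: float
    o_exo: float = 0.0
    a_exo: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"state component {name} must be finite")
            if v < 0:
                raise ValueError(f"state component {name} must be nonnegative, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (7,):
            raise ValueError("state array must have 7 components")
        return cls(*[float(v) for v in y])


@dataclass(frozen=True)
class InputSignal:
    """Piecewise-constant synaptic drive ``I(t) = I0 + sum of active steps``.

    ``steps`` is a sequence of ``(start, duration, amplitude)`` rectangles
    representing external stressors layered on the basal input.
    """

    baseline: float = 1.0
    steps: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline input I0 must be strictly positive")
        object.__setattr__(self, "steps", tuple(tuple(map(float, s)) for s in self.steps))
        for start, duration, amplitude in self.steps:
            if duration <= 0:
                raise ValueError("step duration must be strictly positive")
            if amplitude < 0:
                raise ValueError("step amplitude must be nonnegative")

    def value(self, t: float) -> float:
        """Evaluate I(t); active on the half-open window [start, start+duration)."""
        v = self.baseline
        for start, duration, amplitude in self.steps:
            if start <= t < start + duration:
                v += amplitude
        return v

    def breakpoints(self) -> list[float]:
        pts: list[float] = []
        for start, duration, _ in self.steps:
            pts.extend((start, start + duration))
        return pts


@dataclass(frozen=True)
class DosePulse:
    """A rectangular drug infusion into one exogenous compartment.

    ``compartment`` is ``"dex"`` (feeds ``o_exo``) or ``"acth"`` (feeds
    ``a_exo``); ``height`` is the constant infusion rate while active.
    """

    compartment: str
    start: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.compartment not in ("dex", "acth"):
            raise ValueError("compartment must be 'dex' or 'acth'")
        if self.width <= 0:
            raise ValueError("pulse width must be strictly positive")
        if self.height < 0:
            raise ValueError("pulse height must be nonnegative")

    def rate(self, t: float) -> float:
        return self.height if self.start <= t < self.start + self.width else 0.0

    def breakpoints(self) -> list[float]:
        return [self.start, self.start + self.width]


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def system_rhs(
    state_now: SystemState | Sequence[float],
    a_delayed: float,
    a_exo_delayed: float,
    I_now: float,
    params: ParameterSet,
) -> np.ndarray:
    """Time derivatives of the five endogenous variables ``(cs, c, a, r, o)``.

    ``a_delayed`` and ``a_exo_delayed`` are the ACTH and cosyntropin levels
    one adrenal delay ``t_d`` in the past; the caller (normally the solver's
    interpolated history) must supply them.  Dexamethasone ``o_exo`` adds to
    cortisol only inside the pituitary terms (feedback and GR production),
    never in the hypothalamic synthesis-target equation, reflecting its poor
    brain penetration.
    """
    if isinstance(state_now, SystemState):
        y = state_now.as_array()
    else:
        y = np.asarray(state_now, dtype=float)
        if y.shape != (7,):
            raise ValueError("state must have 7 components (cs, c, a, r, o, o_exo, a_exo)")
        if np.any(y < 0):
            raise ValueError("state components must be nonnegative")
    if a_delayed is None or a_exo_delayed is None:
        raise ValueError("delayed ACTH values are required (supply 0.0 explicitly if absent)")
    cs, c, a, r, o, o_exo, _ = y
    or_eff = (o + o_exo) * r
    dcs = (crh_synthesis_target(o, params.b, params.c_inf_bar) - cs) / params.t_c
    dc = (
        params.q0 * I_now * release_fraction(cs, params.k)
        + autocrine_upregulation(c, params)
        - params.q2 * c
    )
    da = c * pituitary_feedback(or_eff, params.p2) - params.p3 * a
    dr = gr_production(or_eff, params.p4, params.p5) - params.p6 * r
    do = a_delayed + a_exo_delayed - o
    return np.array([dcs, dc, da, dr, do])


def pharmacokinetics_rhs(x_exo: float, pulse_rate: float, decay: float) -> float:
    """One-compartment kinetics of an exogenous drug: infusion minus first-order loss."""
    if decay <= 0:
        raise ValueError("decay rate must be strictly positive")
    if x_exo < 0:
        raise ValueError("drug level must be nonnegative")
    return pulse_rate - decay * x_exo
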