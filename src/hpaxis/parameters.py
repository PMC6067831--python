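"""Nondimensional parameter set for the HPA-axis model and unit helpers.

The model is fully nondimensionalized: concentrations are scaled by
steady-state reference levels and time is scaled by the clearance rate of
cortisol (half-life ~7.2 min), so one dimensionless time unit corresponds
to 7.2/ln 2 ~ 10.4 minutes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace as _dc_replace
from typing import Any, Iterator, Mapping

__all__ = [
    "ParameterSet",
    "REFERENCE",
    "rate_ratio_from_halflives",
    "minutes_to_dimensionless",
    "dimensionless_to_minutes",
    "CORTISOL_HALFLIFE_MIN",
]

#: Plasma cortisol half-life in minutes used throughout the nondimensionalization.
CORTISOL_HALFLIFE_MIN = 7.2


def rate_ratio_from_halflives(halflife_ref_minutes: float, halflife_drug_minutes: float) -> float:
    """Ratio of first-order decay rates of a drug relative to a reference hormone.

    Decay rate is ln2 / half-life, so the ln2 cancels and the ratio of rates
    equals ``halflife_ref / halflife_drug``.  Used to derive the dimensionless
    clearance constants of exogenous compounds (e.g. dexamethasone with a
    ~240 min half-life against cortisol's ~7.2 min gives 0.03).

    Parameters
    ----------
    halflife_ref_minutes : float
        Half-life of the reference hormone (cortisol), in minutes.
    halflife_drug_minutes : float
        Half-life of the drug, in minutes.
    """
    if halflife_ref_minutes <= 0 or halflife_drug_minutes <= 0:
        raise ValueError("half-lives must be strictly positive")
    return halflife_ref_minutes / halflife_drug_minutes


def minutes_to_dimensionless(t_minutes: float, cortisol_halflife_minutes: float = CORTISOL_HALFLIFE_MIN) -> float:
    """Convert a clock duration in minutes to dimensionless model time.

    Time is scaled by the cortisol elimination rate ln2/half-life, so
    15 min maps to 15*ln2/7.2 = 1.44, the adrenal delay used by default.
    """
    if cortisol_halflife_minutes <= 0:
        raise ValueError("half-life must be strictly positive")
    return t_minutes * math.log(2.0) / cortisol_halflife_minutes


def dimensionless_to_minutes(t: float, cortisol_halflife_minutes: float = CORTISOL_HALFLIFE_MIN) -> float:
    """Inverse of :func:`minutes_to_dimensionless`."""
    return t * cortisol_halflife_minutes / math.log(2.0)


@dataclass(frozen=True)
class ParameterSet:
    """All nondimensional constants of the model.

    Attributes
    ----------
    q0 : maximum CRH release rate in the basal state.
    q1 : circulating-CRH level giving half-maximal self-upregulation.
    q2 : ratio of CRH and cortisol decay rates.
    gc_max : maximum auto/paracrine (self-upregulation) effect of CRH.
    n : Hill coefficient of the CRH self-upregulation function.
    k : coupling between stored CRH and the CRH release rate.
    b : strength of cortisol suppression of CRH synthesis.
    c_inf_bar : asymptotic stored-CRH synthesis target under full cortisol
        suppression (the floor of the synthesis target ``c_inf(o)``).
    t_c : relaxation timescale of the stored-CRH pool (dimensionless).
    p2 : cortisol-GR complex level for half-maximal negative feedback on ACTH.
    p3 : ratio of ACTH and cortisol decay rates.
    p4 : complex level (squared) for half-maximal GR self-upregulation.
    p5 : basal GR production rate.
    p6 : ratio of GR and cortisol decay rates.
    t_d : adrenal response delay (dimensionless; 1.44 ~ 15 min).
    I0 : basal synaptic input to the PVN.
    p7 : dexamethasone clearance rate relative to cortisol (~7.2/240).
    p8 : cosyntropin clearance rate relative to cortisol.

    ``c_inf_bar`` and ``t_c`` have no universally agreed literature values;
    the defaults here were fixed once by the calibration script
    (``scripts/calibrate.py``) so that the reference set is bistable with
    two oscillating attractors and a dexamethasone challenge discriminates
    the two basins.  Both remain ordinary, overridable fields.
    """

    q0: float = 28.0
    q1: float = 0.04
    q2: float = 1.8
    gc_max: float = 42.0
    n: float = 5.0
    k: float = 2.83
    b: float = 0.6
    c_inf_bar: float = 0.18
    t_c: float = 120.0
    p2: float = 15.0
    p3: float = 7.2
    p4: float = 0.05
    p5: float = 0.11
    p6: float = 2.9
    t_d: float = 1.44
    I0: float = 1.0
    p7: float = 0.03
    p8: float = 1.7

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise TypeError(f"parameter {f.name} must be a number, got {v!r}")
            if math.isnan(v) or math.isinf(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v}")
        if self.c_inf_bar < 0:
            raise ValueError("c_inf_bar must be >= 0")
        if self.t_d < 0:
            raise ValueError("t_d must be >= 0")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")
        for name in ("q0", "q1", "q2", "gc_max", "k", "b", "t_c",
                     "p2", "p3", "p4", "p5", "p6", "I0", "p7", "p8"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")

    # -- convenience -------------------------------------------------------
    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields replaced (and revalidated)."""
        return _dc_replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(
                f"unknown parameter key(s) {sorted(unknown)}; valid keys are {sorted(known)}"
            )
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())


#: The reference nondimensional parameter set.  Printed literature values for
#: everything except ``c_inf_bar`` and ``t_c``, which are the repository's
#: calibrated defaults (see scripts/calibrate.py and docs/methods.md).
REFERENCE = ParameterSet()
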