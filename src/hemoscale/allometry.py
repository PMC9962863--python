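"""Allometric power-law scaling of cell-lifespan parameters.

Physiological times tend to follow ``theta = a * W^b`` across mammals
(W = body weight).  Lifespans of megakaryocytes, platelets,
reticulocytes and red cells estimated in the rat are translated to
humans by log-log least squares and exponent-based rescaling; capacity
(Smax) and sensitivity (SC50) parameters are species-conserved and are
copied unchanged, while blood-cell baselines and MCH are fixed to
observed human values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .hematopoiesis import PDParameterSet

__all__ = [
    "SpeciesPoint",
    "AllometricFit",
    "fit_power_law",
    "scale_parameter",
    "build_scaled_human_pd",
    "LIFESPAN_FIELDS",
]

#: PDParameterSet fields that are physiological times subject to scaling
LIFESPAN_FIELDS = ("t_mp", "t_plt", "t_ret", "t_rbc")

#: effect/rate parameters copied across species unchanged
CONSERVED_FIELDS = (
    "ke", "km_diff", "smax_rm1", "smax_rm2", "smax_epo1",
    "sc50_rm", "sc50_epo", "imax_epo", "ic50_epo",
)

#: observed-human fields replaced rather than scaled
HUMAN_FIXED_FIELDS = ("plt0", "rbc0", "mch")


class AllometryError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesPoint:
    """One species' body weight and parameter value (native units)."""

    species: str
    body_weight: float
    value: float

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise AllometryError("body_weight must be > 0")
        if self.value <= 0:
            raise AllometryError("value must be > 0 (log-log regression)")


@dataclass(frozen=True)
class AllometricFit:
    """Power law ``value = a * W^b`` with the log-scale R^2."""

    coefficient_a: float
    exponent_b: float
    r_squared: float
    n_points: int = 0

    def predict(self, body_weight) -> np.ndarray | float:
        return self.coefficient_a * np.asarray(body_weight, float) ** self.exponent_b


def fit_power_law(points: Sequence[SpeciesPoint]) -> AllometricFit:
    """Ordinary least squares of log10(value) on log10(body weight)."""
    if len(points) < 2:
        raise AllometryError("need at least 2 species points")
    w = np.array([p.body_weight for p in points])
    v = np.array([p.value for p in points])
    if np.unique(w).size < 2:
        raise AllometryError("species body weights must not coincide")
    lw, lv = np.log10(w), np.log10(v)
    res = stats.linregress(lw, lv)
    if np.ptp(lv) == 0:  # constant value: R^2 defined as exact fit
        r2 = 1.0
    else:
        r2 = float(res.rvalue**2)
    return AllometricFit(
        coefficient_a=float(10.0**res.intercept),
        exponent_b=float(res.slope),
        r_squared=r2,
        n_points=len(points),
    )


def scale_parameter(
    value_ref: float, bw_ref: float, bw_target: float, exponent_b: float
) -> float:
    """Rescale a reference species' value along ``theta = a W^b``.

    The coefficient cancels: ``theta_t = theta_r * (W_t / W_r)^b``.
    """
    if value_ref <= 0 or bw_ref <= 0 or bw_target <= 0:
        raise AllometryError("value and body weights must be > 0")
    return value_ref * (bw_target / bw_ref) ** exponent_b


def build_scaled_human_pd(
    rat_params: PDParameterSet,
    exponents: Mapping[str, float],
    bw_rat: float,
    bw_human: float,
    human_fixed: Mapping[str, float],
) -> PDParameterSet:
    """Translate a rat PD parameter set to a human one.

    Each lifespan field must either have an entry in ``exponents``
    (scaled by ``(bw_human / bw_rat)^b``) or a direct human value in
    ``human_fixed``; ``plt0``, ``rbc0`` and ``mch`` must always be
    supplied in ``human_fixed``.  Effect parameters are copied.
    """
    unknown = set(exponents) - set(LIFESPAN_FIELDS)
    if unknown:
        raise AllometryError(f"exponents given for non-lifespan fields: {sorted(unknown)}")
    allowed_fixed = set(HUMAN_FIXED_FIELDS) | set(LIFESPAN_FIELDS)
    unknown = set(human_fixed) - allowed_fixed
    if unknown:
        raise AllometryError(f"unexpected human_fixed fields: {sorted(unknown)}")
    updates: dict[str, float] = {}
    for name in LIFESPAN_FIELDS:
        if name in human_fixed:
            updates[name] = float(human_fixed[name])
        elif name in exponents:
            updates[name] = scale_parameter(
                getattr(rat_params, name), bw_rat, bw_human, exponents[name]
            )
        else:
            raise AllometryError(
                f"missing exponent (or fixed human value) for lifespan {name!r}"
            )
    for name in HUMAN_FIXED_FIELDS:
        if name not in human_fixed:
            raise AllometryError(f"human_fixed must supply {name!r}")
        updates[name] = float(human_fixed[name])
    return replace(rat_params, **updates)
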