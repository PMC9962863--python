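"""Pharmacokinetic models for rHuEPO and romiplostim.

Both drugs bind a finite receptor pool (EPO-R on erythroid precursors,
c-Mpl on platelets/megakaryocytes), which makes their disposition
nonlinear at therapeutic concentrations.  Two reductions of the full
target-mediated drug disposition (TMDD) system are implemented:

* a Michaelis-Menten TMDD hybrid used for the rat parameterizations,
  where the receptor route appears as a saturable elimination term
  ``V_M * C / (K_M + C)`` and the total receptor pool is the constant
  ``R_TOT = V_M / (V_C * K_INT)``;
* quasi-equilibrium (QE) TMDD models used for the human
  parameterizations, where the free concentration is the positive root
  of the binding quadratic and the drug-receptor complex is eliminated
  by internalization.

Units: time in hours throughout; rHuEPO amounts in IU and concentrations
in IU/L (numerically identical to mIU/mL); romiplostim amounts in µg and
concentrations in ng/mL (= µg/L).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DoseEvent",
    "EpoRatPK",
    "RomiRatPK",
    "EpoHumanPK",
    "RomiHumanPK",
    "PKState",
    "ConcProfile",
    "qe_free_concentration",
    "rtot_from_mm",
    "romi_receptor_pool",
    "rat_mm_rhs",
    "human_epo_rhs",
    "human_romi_rhs",
    "apply_dose",
    "simulate_pk",
]

EPO = "EPO"
ROMI = "ROMI"
IV = "IV"
SC = "SC"

# clamp band for floating-point cancellation in the QE root
_NEG_CLAMP = -1e-12


class PKValidationError(ValueError):
    """Invalid parameter or state input to a PK operation."""


class PKSolverError(RuntimeError):
    """ODE integration failure, annotated with dosing context."""


@dataclass(frozen=True)
class DoseEvent:
    """A timed drug administration.

    Parameters
    ----------
    time : float
        Hours since simulation start.
    drug : str
        ``"EPO"`` or ``"ROMI"``.
    route : str
        ``"IV"`` (into the central compartment) or ``"SC"`` (into the
        absorption depot, scaled by bioavailability).
    amount_per_kg : float
        IU/kg for EPO, µg/kg for romiplostim.
    body_weight : float
        Subject body weight in kg.
    """

    time: float
    drug: str
    route: str
    amount_per_kg: float
    body_weight: float = 70.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise PKValidationError(f"dose time must be >= 0, got {self.time}")
        if self.amount_per_kg < 0:
            raise PKValidationError("amount_per_kg must be >= 0")
        if self.body_weight <= 0:
            raise PKValidationError("body_weight must be > 0")
        if self.drug not in (EPO, ROMI):
            raise PKValidationError(f"unknown drug {self.drug!r}")
        if self.route not in (IV, SC):
            raise PKValidationError(f"unknown route {self.route!r}")

    @property
    def amount(self) -> float:
        """Absolute dose (IU or µg)."""
        return self.amount_per_kg * self.body_weight


def _require_positive(obj, names) -> None:
    for name in names:
        if getattr(obj, name) <= 0:
            raise PKValidationError(f"{type(obj).__name__}.{name} must be > 0")


@dataclass(frozen=True)
class EpoRatPK:
    """Rat rHuEPO Michaelis-Menten TMDD parameters."""

    KA_E: float
    F_E: float
    CL_EPO: float
    V_CEPO: float
    V_MEPO: float
    K_MEPO: float
    K_CPEPO: float
    K_PCEPO: float
    K_INTE: float

    drug = EPO

    def __post_init__(self) -> None:
        _require_positive(
            self, ["KA_E", "CL_EPO", "V_CEPO", "K_MEPO", "K_INTE"]
        )
        if not 0 < self.F_E <= 1:
            raise PKValidationError("F_E must be in (0, 1]")
        if self.V_MEPO < 0 or self.K_CPEPO < 0 or self.K_PCEPO < 0:
            raise PKValidationError("rate parameters must be >= 0")

    @property
    def bioavailability(self) -> float:
        return self.F_E


@dataclass(frozen=True)
class RomiRatPK:
    """Rat romiplostim Michaelis-Menten TMDD parameters."""

    KA_RM: float
    F_RM: float
    CL_RM: float
    V_CRM: float
    V_MRM: float
    K_MRM: float
    K_CPRM: float
    K_PCRM: float
    K_INTR: float

    drug = ROMI

    def __post_init__(self) -> None:
        _require_positive(self, ["KA_RM", "CL_RM", "V_CRM", "K_MRM", "K_INTR"])
        if not 0 < self.F_RM <= 1:
            raise PKValidationError("F_RM must be in (0, 1]")
        if self.V_MRM < 0 or self.K_CPRM < 0 or self.K_PCRM < 0:
            raise PKValidationError("rate parameters must be >= 0")

    @property
    def bioavailability(self) -> float:
        return self.F_RM


@dataclass(frozen=True)
class EpoHumanPK:
    """Human rHuEPO quasi-equilibrium TMDD parameters.

    Two-compartment disposition (``V2E`` central, ``V3E`` peripheral,
    ``Q_E`` distribution clearance) with linear clearance ``CL_E``, a
    receptor pool with baseline ``RTOT0`` turning over at ``KDEG_E`` and
    complex internalization at ``KINT_E``.
    """

    CL_E: float
    KA_E: float
    F_E: float
    V2E: float
    V3E: float
    Q_E: float
    RTOT0: float
    KM_E: float
    KINT_E: float
    KDEG_E: float

    drug = EPO

    def __post_init__(self) -> None:
        _require_positive(
            self,
            ["CL_E", "KA_E", "V2E", "V3E", "Q_E", "KM_E", "KINT_E", "KDEG_E"],
        )
        if self.RTOT0 < 0:
            raise PKValidationError("RTOT0 must be >= 0")
        if not 0 < self.F_E <= 1:
            raise PKValidationError("F_E must be in (0, 1]")

    @property
    def bioavailability(self) -> float:
        return self.F_E


@dataclass(frozen=True)
class RomiHumanPK:
    """Human romiplostim quasi-equilibrium TMDD parameters.

    The c-Mpl receptor pool is carried by platelets: ``XI_R`` is the
    receptor content per platelet (fg/platelet), so the receptor
    concentration scales with the platelet count.
    """

    CL_R: float
    V2R: float
    KCPR: float
    KPCR: float
    KA_RM: float
    F_RM: float
    KM_R: float
    XI_R: float
    KINT_R: float

    drug = ROMI

    def __post_init__(self) -> None:
        _require_positive(self, ["CL_R", "V2R", "KA_RM", "KM_R", "KINT_R"])
        if self.XI_R < 0 or self.KCPR < 0 or self.KPCR < 0:
            raise PKValidationError("XI_R, KCPR, KPCR must be >= 0")
        if not 0 < self.F_RM <= 1:
            raise PKValidationError("F_RM must be in (0, 1]")

    @property
    def bioavailability(self) -> float:
        return self.F_RM


PKParameterSet = EpoRatPK | RomiRatPK | EpoHumanPK | RomiHumanPK


@dataclass(frozen=True)
class PKState:
    """Drug amounts by compartment (plus the receptor pool where dynamic)."""

    depot_amount: float = 0.0
    central_amount: float = 0.0
    peripheral_amount: float = 0.0
    receptor_total_conc: float | None = None


@dataclass(frozen=True)
class ConcProfile:
    """Free drug concentration on a time grid."""

    time: np.ndarray
    free_conc: np.ndarray
    drug: str
    unit: str

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.free_conc, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "free_conc", c)
        if t.shape != c.shape:
            raise PKValidationError("time and free_conc shapes differ")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise PKValidationError("time grid must be strictly increasing")
        if np.any(c < _NEG_CLAMP * 1e3):
            raise PKValidationError("free_conc must be non-negative")

    @classmethod
    def zeros(cls, time: np.ndarray, drug: str) -> "ConcProfile":
        unit = "IU/L" if drug == EPO else "ng/mL"
        t = np.asarray(time, dtype=float)
        return cls(t, np.zeros_like(t), drug, unit)

    def interp(self, t) -> np.ndarray | float:
        """Linear interpolation of the free concentration."""
        return np.interp(t, self.time, self.free_conc)


def qe_free_concentration(c_tot, r_tot, km):
    """Free drug concentration under the quasi-equilibrium binding model.

    Solves ``C^2 + (r_tot + km - c_tot) C - km c_tot = 0`` for the
    non-negative root

    ``C = 0.5 * [(c_tot - r_tot - km) + sqrt((c_tot - r_tot - km)^2 + 4 km c_tot)]``

    Accepts scalars or arrays; ``0 <= C <= c_tot`` always holds.
    """
    c_tot = np.asarray(c_tot, dtype=float)
    r_tot = np.asarray(r_tot, dtype=float)
    if np.any(c_tot < 0) or np.any(r_tot < 0):
        raise PKValidationError("c_tot and r_tot must be >= 0")
    if np.any(np.asarray(km) <= 0):
        raise PKValidationError("km must be > 0")
    b = c_tot - r_tot - km
    disc = np.sqrt(b * b + 4.0 * km * c_tot)
    # the textbook root cancels catastrophically when b << 0 (receptor
    # excess); the equivalent product form stays accurate there
    c = np.where(
        b >= 0,
        0.5 * (b + disc),
        np.divide(
            2.0 * km * c_tot, disc - b,
            out=np.zeros_like(disc), where=(disc - b) > 0,
        ),
    )
    # cancellation can produce tiny negatives when c_tot ~ 0
    c = np.where((c < 0) & (c > _NEG_CLAMP), 0.0, c)
    if c.ndim == 0:
        return float(c)
    return c


def rtot_from_mm(v_max: float, v_c: float, k_int: float) -> float:
    """Total receptor concentration implied by Michaelis-Menten elimination.

    In the QE reduction the maximal elimination rate is
    ``V_max = K_INT * R_TOT * V_C``, hence ``R_TOT = V_max / (V_C * K_INT)``.
    """
    if v_max < 0:
        raise PKValidationError("v_max must be >= 0")
    if v_c <= 0 or k_int <= 0:
        raise PKValidationError("v_c and k_int must be > 0")
    return v_max / (v_c * k_int)


def romi_receptor_pool(xi_r: float, plt_1e12_per_l: float) -> float:
    """c-Mpl receptor concentration (ng/mL) carried by the platelet pool.

    ``xi_r`` fg/platelet x platelet count (1e12 cells/L): fg/L -> ng/mL
    is a factor 1e-9, so the product picks up 1e12 * 1e-9 = 1e3.
    """
    if xi_r < 0 or plt_1e12_per_l < 0:
        raise PKValidationError("receptor inputs must be >= 0")
    return xi_r * plt_1e12_per_l * 1e3


# ---------------------------------------------------------------------------
# right-hand sides (array core + PKState wrappers)

def _rat_rhs_array(y: np.ndarray, p: EpoRatPK | RomiRatPK) -> np.ndarray:
    if isinstance(p, EpoRatPK):
        ka, cl, v_c = p.KA_E, p.CL_EPO, p.V_CEPO
        v_m, k_m = p.V_MEPO, p.K_MEPO
        k_cp, k_pc, k_int = p.K_CPEPO, p.K_PCEPO, p.K_INTE
    else:
        ka, cl, v_c = p.KA_RM, p.CL_RM, p.V_CRM
        v_m, k_m = p.V_MRM, p.K_MRM
        k_cp, k_pc, k_int = p.K_CPRM, p.K_PCRM, p.K_INTR
    dep, a_c, a_p = y
    c_tot = max(a_c, 0.0) / v_c
    r_tot = rtot_from_mm(v_m, v_c, k_int)
    c = qe_free_concentration(c_tot, r_tot, k_m)
    mm = v_m * c / (k_m + c)
    d_dep = -ka * dep
    d_ac = ka * dep - cl * c - mm - k_cp * v_c * c + k_pc * a_p
    d_ap = k_cp * v_c * c - k_pc * a_p
    return np.array([d_dep, d_ac, d_ap])


def _human_epo_rhs_array(y: np.ndarray, p: EpoHumanPK) -> np.ndarray:
    dep, a_c, a_p, r_tot = y
    r_tot = max(r_tot, 0.0)
    c_tot = max(a_c, 0.0) / p.V2E
    c = qe_free_concentration(c_tot, r_tot, p.KM_E)
    rc = r_tot * c / (p.KM_E + c)
    ksyn = p.KDEG_E * p.RTOT0
    d_dep = -p.KA_E * dep
    d_ac = (
        p.KA_E * dep
        - p.CL_E * c
        - p.Q_E * c
        + (p.Q_E / p.V3E) * a_p
        - p.KINT_E * rc * p.V2E
    )
    d_ap = p.Q_E * c - (p.Q_E / p.V3E) * a_p
    d_r = ksyn - p.KDEG_E * r_tot - (p.KINT_E - p.KDEG_E) * rc
    return np.array([d_dep, d_ac, d_ap, d_r])


def _human_romi_rhs_array(
    y: np.ndarray, p: RomiHumanPK, plt_1e12_per_l: float
) -> np.ndarray:
    dep, a_c, a_p = y
    c_tot = max(a_c, 0.0) / p.V2R
    r_tot = romi_receptor_pool(p.XI_R, plt_1e12_per_l)
    c = qe_free_concentration(c_tot, r_tot, p.KM_R)
    rc = r_tot * c / (p.KM_R + c)
    d_dep = -p.KA_RM * dep
    d_ac = (
        p.KA_RM * dep
        - p.CL_R * c
        - p.KCPR * p.V2R * c
        + p.KPCR * a_p
        - p.KINT_R * rc * p.V2R
    )
    d_ap = p.KCPR * p.V2R * c - p.KPCR * a_p
    return np.array([d_dep, d_ac, d_ap])


def _state_to_array(state: PKState, params: PKParameterSet) -> np.ndarray:
    base = [state.depot_amount, state.central_amount, state.peripheral_amount]
    if isinstance(params, EpoHumanPK):
        r = state.receptor_total_conc
        base.append(params.RTOT0 if r is None else r)
    return np.array(base, dtype=float)


def _array_to_state(y: np.ndarray, params: PKParameterSet) -> PKState:
    r = float(y[3]) if isinstance(params, EpoHumanPK) else None
    return PKState(float(y[0]), float(y[1]), float(y[2]), r)


def rat_mm_rhs(state: PKState, params: EpoRatPK | RomiRatPK) -> PKState:
    """Time-derivatives of the rat Michaelis-Menten TMDD model."""
    d = _rat_rhs_array(_state_to_array(state, params), params)
    return PKState(*d)


def human_epo_rhs(state: PKState, params: EpoHumanPK) -> PKState:
    """Time-derivatives of the human rHuEPO QE-TMDD model."""
    d = _human_epo_rhs_array(_state_to_array(state, params), params)
    return PKState(d[0], d[1], d[2], d[3])


def human_romi_rhs(
    state: PKState, params: RomiHumanPK, platelet_pool: float | None = None
) -> PKState:
    """Time-derivatives of the human romiplostim QE-TMDD model.

    ``platelet_pool`` is the platelet count in 1e12 cells/L; ``None``
    falls back to a typical baseline of 0.23.
    """
    plt = 0.23 if platelet_pool is None else platelet_pool
    d = _human_romi_rhs_array(_state_to_array(state, params), params, plt)
    return PKState(*d)


def apply_dose(
    state: PKState, event: DoseEvent, params: PKParameterSet
) -> PKState:
    """Instantaneous dosing: IV into central, SC into the depot (times F)."""
    if event.route == IV:
        return replace(
            state, central_amount=state.central_amount + event.amount
        )
    if event.route == SC:
        return replace(
            state,
            depot_amount=state.depot_amount
            + params.bioavailability * event.amount,
        )
    raise PKValidationError(f"unknown route {event.route!r}")


def free_concentration(y: np.ndarray, params: PKParameterSet,
                       platelet_pool: float = 0.23) -> float:
    """Free concentration implied by a raw state vector."""
    if isinstance(params, (EpoRatPK, RomiRatPK)):
        if isinstance(params, EpoRatPK):
            v_c, v_m, k_int, k_m = (
                params.V_CEPO, params.V_MEPO, params.K_INTE, params.K_MEPO
            )
        else:
            v_c, v_m, k_int, k_m = (
                params.V_CRM, params.V_MRM, params.K_INTR, params.K_MRM
            )
        r_tot = rtot_from_mm(v_m, v_c, k_int)
        return qe_free_concentration(max(y[1], 0.0) / v_c, r_tot, k_m)
    if isinstance(params, EpoHumanPK):
        return qe_free_concentration(
            max(y[1], 0.0) / params.V2E, max(y[3], 0.0), params.KM_E
        )
    r_tot = romi_receptor_pool(params.XI_R, platelet_pool)
    return qe_free_concentration(max(y[1], 0.0) / params.V2R, r_tot,
                                 params.KM_R)


def simulate_pk(
    params: PKParameterSet,
    events: Sequence[DoseEvent],
    grid: np.ndarray,
    *,
    platelet_pool: float | Callable[[float], float] | None = None,
    receptor_partition: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> ConcProfile:
    """Integrate a PK model over a dosing schedule.

    Integration restarts at every dose time so the bolus discontinuities
    never cross a solver step.  Events whose ``drug`` does not match
    ``params.drug`` are ignored, so a mixed combination-therapy schedule
    can be passed unchanged.  The concentration reported at a dose time
    is the post-dose value.

    For the human romiplostim model the platelet-borne c-Mpl pool
    enters the quasi-equilibrium partition only when
    ``receptor_partition`` is set; by default the reported (and
    PD-driving) concentration is on the total scale, the scale on which
    the SC50 of the stimulus was estimated.  ``platelet_pool`` (a count
    in 1e12 cells/L, or a callable of time) only matters with the
    partition enabled.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise PKValidationError("grid must be 1-D strictly increasing")
    events = sorted(
        (e for e in events if e.drug == params.drug), key=lambda e: e.time
    )
    if events and events[-1].time > grid[-1]:
        raise PKValidationError("grid must cover all dose events")

    plt_of_t: Callable[[float], float]
    if isinstance(params, RomiHumanPK) and not receptor_partition:
        plt_of_t = lambda t: 0.0  # noqa: E731  (no QE partition: free = total)
    elif callable(platelet_pool):
        plt_of_t = platelet_pool
    else:
        fixed_plt = 0.23 if platelet_pool is None else float(platelet_pool)
        plt_of_t = lambda t: fixed_plt  # noqa: E731

    if isinstance(params, (EpoRatPK, RomiRatPK)):
        rhs = lambda t, y: _rat_rhs_array(y, params)  # noqa: E731
    elif isinstance(params, EpoHumanPK):
        rhs = lambda t, y: _human_epo_rhs_array(y, params)  # noqa: E731
    else:
        rhs = lambda t, y: _human_romi_rhs_array(  # noqa: E731
            y, params, plt_of_t(t)
        )

    y = _state_to_array(PKState(), params)
    breakpoints = sorted({grid[0]} | {e.time for e in events} | {grid[-1]})
    breakpoints = [t for t in breakpoints if grid[0] <= t <= grid[-1]]

    out = np.empty_like(grid)
    filled = np.zeros(grid.shape, dtype=bool)
    ev_iter = iter(events)
    pending = next(ev_iter, None)

    for i, t0 in enumerate(breakpoints):
        # apply all doses scheduled exactly at t0
        while pending is not None and pending.time == t0:
            state = _array_to_state(y, params)
            y = _state_to_array(apply_dose(state, pending, params), params)
            pending = next(ev_iter, None)
        if i == len(breakpoints) - 1:
            sel = filled == False  # noqa: E712  (remaining points)
            sel &= grid >= t0
            for j in np.where(sel)[0]:
                out[j] = free_concentration(y, params, plt_of_t(grid[j]))
                filled[j] = True
            break
        t1 = breakpoints[i + 1]
        sel = (grid >= t0) & (grid < t1) & ~filled
        t_eval = grid[sel]
        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, t_eval=None,
            dense_output=True, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise PKSolverError(
                f"PK integration failed on [{t0}, {t1}] h "
                f"(segment {i}): {sol.message}"
            )
        for j, tg in zip(np.where(sel)[0], t_eval):
            out[j] = free_concentration(
                sol.sol(tg), params, plt_of_t(tg)
            )
            filled[j] = True
        y = sol.y[:, -1]

    unit = "IU/L" if params.drug == EPO else "ng/mL"
    out = np.clip(out, 0.0, None)
    return ConcProfile(grid, out, params.drug, unit)
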