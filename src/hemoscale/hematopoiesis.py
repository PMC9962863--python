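"""Lifespan-based catenary model of erythropoiesis and thrombopoiesis.

A bipotent megakaryocyte-erythroid progenitor (MEP) pool feeds two
lineages:

* erythroid: BFU-E -> CFU-E -> normoblast (three precursor stages of
  residence ``T_EP`` each) -> reticulocyte (``T_RET``) -> red cell
  (``T_RBC``), with hemoglobin an algebraic output ``MCH * RBC``;
* megakaryocyte/platelet: ``n_MK`` aging compartments of total
  residence ``T_MP`` followed by ``n_PLT`` platelet compartments of
  total residence ``T_PLT`` (Erlang-distributed transit).

rHuEPO steers MEP fate toward the erythroid branch (stimulates the
differentiation rate ``KE``) and slows reticulocyte maturation;
romiplostim expands MEP production (``Kin1``) and the MK-committed
inflow (``Kin2``).  The competition for the shared MEP pool is what
generates EPO resistance: sustained stimulation depletes the
progenitors and the hemoglobin response fades under continued dosing.

Cell concentrations are carried in units of 1e12 cells/L (so a platelet
baseline of 0.23e12 cells/L is the number 0.23); time is in hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .pk import ConcProfile

__all__ = [
    "PDParameterSet",
    "DerivedBaselines",
    "HematoState",
    "PDTrajectory",
    "stimulus",
    "inhibition",
    "derive_baselines",
    "initial_state",
    "pd_rhs",
    "hgb_from_rbc",
    "simulate_pd",
]


class PDValidationError(ValueError):
    pass


class BaselineInfeasibleError(PDValidationError):
    """Raised when the printed constants admit no non-negative closure."""


class PDSolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class PDParameterSet:
    """Hematopoiesis model constants.

    All residence times in hours; ``ke`` and ``km_diff`` are the
    first-order MEP differentiation rate constants into the erythroid
    and megakaryocyte lineages (1/h); baselines ``plt0``/``rbc0`` in
    1e12 cells/L; ``mch`` in pg/cell.  ``km_diff`` is the model's "KM"
    differentiation constant, renamed to avoid colliding with the
    Michaelis constants of the PK layer.
    """

    t_mp: float
    t_plt: float
    plt0: float
    t_rbc: float
    t_ret: float
    rbc0: float
    ke: float
    km_diff: float
    smax_rm1: float
    smax_rm2: float
    smax_epo1: float
    sc50_rm: float
    sc50_epo: float
    imax_epo: float
    ic50_epo: float
    mch: float
    t_ep: float = 48.0
    n_mk: int = 10
    n_plt: int = 10
    n_ery_precursors: int = 3

    def __post_init__(self) -> None:
        for name in (
            "t_mp", "t_plt", "plt0", "t_rbc", "t_ret", "rbc0", "ke",
            "sc50_rm", "sc50_epo", "ic50_epo", "mch", "t_ep",
        ):
            if getattr(self, name) <= 0:
                raise PDValidationError(f"{name} must be > 0")
        for name in ("km_diff", "smax_rm1", "smax_rm2", "smax_epo1"):
            if getattr(self, name) < 0:
                raise PDValidationError(f"{name} must be >= 0")
        if not 0 <= self.imax_epo <= 1:
            raise PDValidationError("imax_epo must be in [0, 1]")
        for name in ("n_mk", "n_plt", "n_ery_precursors"):
            if getattr(self, name) < 1:
                raise PDValidationError(f"{name} must be >= 1")

    @property
    def n_states(self) -> int:
        return 3 + self.n_ery_precursors + self.n_mk + self.n_plt


@dataclass(frozen=True)
class DerivedBaselines:
    """Steady-state closure of the drug-free system.

    ``erythroid_flux = RBC0 / T_RBC`` fixes the MEP pool via
    ``MEP0 = flux / KE``; ``Kin1`` balances total MEP efflux;
    ``Kin2 = PLT0 / T_PLT - KM * MEP0`` is the direct MK-committed
    production needed on top of MEP differentiation.  Units:
    1e12 cells/L and 1e12 cells/L/h.
    """

    mep0: float
    kin1: float
    kin2: float
    erythroid_flux: float
    mk_flux: float


def stimulus(conc, smax: float, sc50: float):
    """Stimulatory Hill factor ``1 + smax * C / (sc50 + C)``, in [1, 1+smax]."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise PDValidationError("conc must be >= 0")
    if sc50 <= 0 or smax < 0:
        raise PDValidationError("sc50 must be > 0 and smax >= 0")
    out = 1.0 + smax * conc / (sc50 + conc)
    return float(out) if out.ndim == 0 else out


def inhibition(conc, imax: float, ic50: float):
    """Inhibitory Hill factor ``1 - imax * C / (ic50 + C)``, in (1-imax, 1]."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise PDValidationError("conc must be >= 0")
    if ic50 <= 0 or not 0 <= imax <= 1:
        raise PDValidationError("ic50 must be > 0 and imax in [0, 1]")
    out = 1.0 - imax * conc / (ic50 + conc)
    return float(out) if out.ndim == 0 else out


def derive_baselines(params: PDParameterSet) -> DerivedBaselines:
    """Close the drug-free steady state from the printed constants."""
    flux = params.rbc0 / params.t_rbc
    mep0 = flux / params.ke
    kin1 = mep0 * (params.ke + params.km_diff)
    mk_flux = params.plt0 / params.t_plt
    kin2 = mk_flux - params.km_diff * mep0
    if kin2 < 0:
        raise BaselineInfeasibleError(
            "infeasible baseline: MK differentiation exceeds platelet "
            f"turnover (KM*MEP0 = {params.km_diff * mep0:.3g} > "
            f"PLT0/T_PLT = {mk_flux:.3g})"
        )
    return DerivedBaselines(mep0, kin1, kin2, flux, mk_flux)


class HematoState:
    """View over the flat ODE state vector.

    Layout: ``[MEP, precursors (n_ery), RET, RBC, MK (n_mk), PLT (n_plt)]``.
    """

    def __init__(self, vec: np.ndarray, params: PDParameterSet):
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (params.n_states,):
            raise PDValidationError(
                f"state vector must have {params.n_states} entries"
            )
        self.vec = vec
        self.params = params

    @property
    def mep(self) -> float:
        return float(self.vec[0])

    @property
    def precursors(self) -> np.ndarray:
        return self.vec[1 : 1 + self.params.n_ery_precursors]

    @property
    def ret(self) -> float:
        return float(self.vec[1 + self.params.n_ery_precursors])

    @property
    def rbc(self) -> float:
        return float(self.vec[2 + self.params.n_ery_precursors])

    @property
    def mk(self) -> np.ndarray:
        i = 3 + self.params.n_ery_precursors
        return self.vec[i : i + self.params.n_mk]

    @property
    def plt(self) -> np.ndarray:
        i = 3 + self.params.n_ery_precursors + self.params.n_mk
        return self.vec[i : i + self.params.n_plt]

    @property
    def plt_total(self) -> float:
        return float(self.plt.sum())

    @property
    def hgb(self) -> float:
        return hgb_from_rbc(self.rbc, self.params.mch)


def initial_state(
    params: PDParameterSet, baselines: DerivedBaselines
) -> HematoState:
    """Drug-free steady state (a fixed point of :func:`pd_rhs`)."""
    vec = np.empty(params.n_states)
    vec[0] = baselines.mep0
    vec[1 : 1 + params.n_ery_precursors] = (
        baselines.erythroid_flux * params.t_ep
    )
    vec[1 + params.n_ery_precursors] = baselines.erythroid_flux * params.t_ret
    vec[2 + params.n_ery_precursors] = params.rbc0
    i = 3 + params.n_ery_precursors
    vec[i : i + params.n_mk] = baselines.mk_flux * params.t_mp / params.n_mk
    i += params.n_mk
    vec[i : i + params.n_plt] = params.plt0 / params.n_plt
    return HematoState(vec, params)


def pd_rhs(
    state,
    c_epo: float,
    c_romi: float,
    params: PDParameterSet,
    baselines: DerivedBaselines,
) -> np.ndarray:
    """Time-derivatives of the full hematopoiesis state.

    ``state`` may be a :class:`HematoState` or the raw vector; ``c_epo``
    in mIU/mL (= IU/L), ``c_romi`` in ng/mL.
    """
    y = state.vec if isinstance(state, HematoState) else np.asarray(state)
    return _pd_rhs_array(y, c_epo, c_romi, params, baselines)


def _pd_rhs_array(y, c_epo, c_romi, params, baselines) -> np.ndarray:
    n_ery, n_mk, n_plt = (
        params.n_ery_precursors, params.n_mk, params.n_plt
    )
    s_e = 1.0 + params.smax_epo1 * c_epo / (params.sc50_epo + c_epo)
    s_r1 = 1.0 + params.smax_rm1 * c_romi / (params.sc50_rm + c_romi)
    s_r2 = 1.0 + params.smax_rm2 * c_romi / (params.sc50_rm + c_romi)
    inh = 1.0 - params.imax_epo * c_epo / (params.ic50_epo + c_epo)

    ke_eff = params.ke * s_e
    mep = y[0]
    prec = y[1 : 1 + n_ery]
    ret = y[1 + n_ery]
    rbc = y[2 + n_ery]
    i_mk = 3 + n_ery
    mk = y[i_mk : i_mk + n_mk]
    plt = y[i_mk + n_mk : i_mk + n_mk + n_plt]

    d = np.empty_like(y)
    d[0] = baselines.kin1 * s_r1 - (ke_eff + params.km_diff) * mep
    # erythroid precursor transit chain
    inflow = ke_eff * mep
    for j in range(n_ery):
        d[1 + j] = inflow - prec[j] / params.t_ep
        inflow = prec[j] / params.t_ep
    ret_out = (ret / params.t_ret) * inh
    d[1 + n_ery] = inflow - ret_out
    d[2 + n_ery] = ret_out - rbc / params.t_rbc
    # megakaryocyte aging chain
    k_mk = n_mk / params.t_mp
    inflow = baselines.kin2 * s_r2 + params.km_diff * mep
    for j in range(n_mk):
        d[i_mk + j] = inflow - k_mk * mk[j]
        inflow = k_mk * mk[j]
    # platelet aging chain
    k_plt = n_plt / params.t_plt
    for j in range(n_plt):
        d[i_mk + n_mk + j] = inflow - k_plt * plt[j]
        inflow = k_plt * plt[j]
    return d


def hgb_from_rbc(rbc: float, mch: float) -> float:
    """Hemoglobin (g/dL) from red cell count (1e12 cells/L) and MCH (pg).

    1e12 cells/L x pg/cell = g/L; divide by 10 for g/dL.
    """
    if np.any(np.asarray(rbc) < 0):
        raise PDValidationError("rbc must be >= 0")
    return np.asarray(rbc) * mch / 10.0 if np.ndim(rbc) else rbc * mch / 10.0


@dataclass(frozen=True)
class PDTrajectory:
    """Observable trajectories on a time grid (units as in the columns)."""

    time: np.ndarray
    rbc: np.ndarray
    plt: np.ndarray
    hgb: np.ndarray
    states: np.ndarray  # full state matrix, one row per grid point

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.time,
                "hgb_g_dl": self.hgb,
                "rbc_1e12_per_l": self.rbc,
                "plt_1e12_per_l": self.plt,
            }
        )


def simulate_pd(
    params: PDParameterSet,
    baselines: DerivedBaselines,
    epo_profile: ConcProfile | None,
    romi_profile: ConcProfile | None,
    grid: np.ndarray,
    *,
    y0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    max_step: float = 24.0,
) -> PDTrajectory:
    """Integrate the hematopoiesis model under given concentration forcing.

    Concentrations are linearly interpolated from the profiles; ``None``
    means no drug.  Starts from the drug-free steady state unless ``y0``
    is given.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise PDValidationError("grid must be 1-D strictly increasing")
    for prof in (epo_profile, romi_profile):
        if prof is not None and (
            prof.time[0] > grid[0] or prof.time[-1] < grid[-1]
        ):
            raise PDValidationError(
                "concentration profile does not cover the grid"
            )

    if epo_profile is None:
        c_epo = lambda t: 0.0  # noqa: E731
    else:
        te, ce = epo_profile.time, epo_profile.free_conc
        c_epo = lambda t: np.interp(t, te, ce)  # noqa: E731
    if romi_profile is None:
        c_romi = lambda t: 0.0  # noqa: E731
    else:
        tr, cr = romi_profile.time, romi_profile.free_conc
        c_romi = lambda t: np.interp(t, tr, cr)  # noqa: E731

    if y0 is None:
        y0 = initial_state(params, baselines).vec.copy()
    else:
        y0 = np.asarray(y0, dtype=float).copy()

    def rhs(t, y):
        return _pd_rhs_array(y, c_epo(t), c_romi(t), params, baselines)

    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1]),
        y0,
        method=method,
        t_eval=grid,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
    )
    if not sol.success:
        raise PDSolverError(f"PD integration failed: {sol.message}")
    states = sol.y.T
    n_ery = params.n_ery_precursors
    rbc = states[:, 2 + n_ery]
    i_plt = 3 + n_ery + params.n_mk
    plt = states[:, i_plt : i_plt + params.n_plt].sum(axis=1)
    hgb = rbc * params.mch / 10.0
    return PDTrajectory(grid, rbc, plt, hgb, states)
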