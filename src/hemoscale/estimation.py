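"""Maximum-likelihood fitting of PD parameters to observation tables.

Naive pooled fitting under a proportional (lognormal) residual error
model: ``value = prediction * eps`` with ``log eps ~ N(0, sigma_a^2)``
and the residual variance profiled out analytically per analyte.  The
optimizer works on transformed parameters (log for positive-valued
parameters, logit for ``imax_epo``) with seeded multi-start, and
approximate standard errors come from the finite-difference curvature
of the objective.  A relative standard error above 50% flags a
parameter as non-identifiable under the given design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .hematopoiesis import PDParameterSet, derive_baselines, simulate_pd
from .synthetic import StudyDesign, study_concentration_profiles

__all__ = [
    "FitSpec",
    "FitResult",
    "StudyPredictor",
    "objective",
    "fit",
    "RSE_FLAG_PERCENT",
]

RSE_FLAG_PERCENT = 50.0
_SIGMA_FLOOR = 1e-6
_PENALTY = 1e10


class EstimationError(ValueError):
    pass


_PD_FIELDS = {f.name for f in fields(PDParameterSet)}


@dataclass(frozen=True)
class FitSpec:
    """What to estimate and from where to start.

    ``free`` maps PD field names to initial values; everything else is
    fixed at the values in ``base``.  Bounds default to two orders of
    magnitude around the initial value (``imax_epo`` to (0, 1)).
    """

    base: PDParameterSet
    free: Mapping[str, float]
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    analytes: Sequence[str] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.free) - _PD_FIELDS
        if unknown:
            raise EstimationError(f"unknown free parameter(s): {sorted(unknown)}")
        if not self.free:
            raise EstimationError("at least one free parameter required")
        for name, (lo, hi) in self.bounds.items():
            if name not in self.free:
                raise EstimationError(f"bounds given for non-free {name!r}")
            if not lo < hi:
                raise EstimationError(f"empty bounds for {name!r}")
            if not lo <= self.free[name] <= hi:
                raise EstimationError(f"initial value outside bounds for {name!r}")

    def resolved_bounds(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name, init in self.free.items():
            if name in self.bounds:
                out[name] = tuple(self.bounds[name])
            elif name == "imax_epo":
                out[name] = (1e-6, 1.0 - 1e-6)
            else:
                out[name] = (init / 100.0, init * 100.0)
        return out


@dataclass
class FitResult:
    estimates: dict[str, float]
    se: dict[str, float]
    rse_percent: dict[str, float]
    objective_value: float
    converged: bool
    non_identifiable: set[str]
    n_evaluations: int
    trace: list[float]

    @property
    def params(self) -> PDParameterSet:
        return replace(self.base_params, **self.estimates)


class StudyPredictor:
    """Model predictions at observation rows, with cached PK profiles.

    The free concentration profiles depend only on the PK parameters
    and the dosing design, not on the PD parameters being estimated, so
    they are computed once per predictor.
    """

    def __init__(
        self,
        design: StudyDesign,
        pk_epo,
        pk_romi,
        *,
        plt_baseline: float | None = None,
        rtol: float = 1e-5,
        atol: float = 1e-7,
        max_step: float = np.inf,
    ):
        self.design = design
        self.rtol = rtol
        self.atol = atol
        self.max_step = max_step
        self._plt_baseline = plt_baseline
        self._grid = None
        self._profiles = None
        self._pk = (pk_epo, pk_romi)

    def _ensure_profiles(self, pd_params: PDParameterSet):
        if self._profiles is None:
            plt0 = (
                pd_params.plt0 if self._plt_baseline is None
                else self._plt_baseline
            )
            self._grid, self._profiles = study_concentration_profiles(
                self.design, *self._pk, plt0
            )

    def __call__(
        self, pd_params: PDParameterSet, observations: pd.DataFrame
    ) -> np.ndarray:
        self._ensure_profiles(pd_params)
        baselines = derive_baselines(pd_params)
        pred = np.empty(len(observations), dtype=float)
        for arm, idx in observations.groupby("arm", sort=False).groups.items():
            epo_prof, romi_prof = self._profiles[arm]
            traj = simulate_pd(
                pd_params, baselines, epo_prof, romi_prof, self._grid,
                rtol=self.rtol, atol=self.atol, max_step=self.max_step,
            )
            series = {
                "EPO_conc": (epo_prof.time, epo_prof.free_conc),
                "ROMI_conc": (romi_prof.time, romi_prof.free_conc),
                "RBC": (traj.time, traj.rbc),
                "PLT": (traj.time, traj.plt),
                "Hgb": (traj.time, traj.hgb),
            }
            sub = observations.loc[idx]
            for analyte, jdx in sub.groupby("analyte", sort=False).groups.items():
                ts, vs = series[analyte]
                rows = observations.loc[jdx]
                pred[observations.index.get_indexer(jdx)] = np.interp(
                    rows["time_h"].to_numpy(), ts, vs
                )
        return pred


def objective(
    pd_params: PDParameterSet,
    observations: pd.DataFrame,
    predictor: Callable[[PDParameterSet, pd.DataFrame], np.ndarray],
) -> float:
    """-2 log-likelihood (up to a parameter-free constant).

    With the per-analyte residual variance profiled at its MLE
    ``sigma_a^2 = mean(log(obs/pred)^2)``, the objective reduces to
    ``sum_a n_a (log sigma_a^2 + 1)``.  The variance is floored at
    ``1e-12`` so an exact fit stays finite.
    """
    obs = observations["value"].to_numpy(dtype=float)
    if np.any(obs <= 0):
        raise EstimationError("observations must be positive")
    try:
        pred = np.asarray(predictor(pd_params, observations), dtype=float)
    except Exception as exc:  # solver blow-up at absurd parameters
        warnings.warn(f"prediction failed, penalizing: {exc}")
        return _PENALTY
    if np.any(~np.isfinite(pred)) or np.any(pred <= 0):
        bad = int(np.sum(pred <= 0))
        warnings.warn(
            f"{bad} non-positive prediction(s) at observation times; "
            "returning penalized objective"
        )
        return _PENALTY + bad
    r = np.log(obs / pred)
    total = 0.0
    for analyte, idx in observations.groupby("analyte", sort=False).groups.items():
        ra = r[observations.index.get_indexer(idx)]
        sigma2 = max(float(np.mean(ra * ra)), _SIGMA_FLOOR**2)
        total += ra.size * (math.log(sigma2) + 1.0)
    return total


def _to_internal(name: str, value: float, lo: float, hi: float) -> float:
    if name == "imax_epo":
        p = min(max((value - lo) / (hi - lo), 1e-12), 1 - 1e-12)
        return math.log(p / (1 - p))
    return math.log(value)


def _from_internal(name: str, z: float, lo: float, hi: float) -> float:
    if name == "imax_epo":
        return lo + (hi - lo) / (1.0 + math.exp(-z))
    return math.exp(z)


def fit(
    spec: FitSpec,
    observations: pd.DataFrame,
    predictor: Callable[[PDParameterSet, pd.DataFrame], np.ndarray],
    *,
    n_starts: int = 5,
    seed: int = 0,
    jitter_sd: float = 0.3,
    maxiter: int = 200,
    xatol: float = 1e-5,
    fatol: float = 1e-9,
) -> FitResult:
    """Multi-start Nelder-Mead minimization of :func:`objective`.

    The first start is the spec's initial values; the remaining starts
    jitter the transformed parameters with seeded Gaussian noise of sd
    ``jitter_sd``.  Bounds are enforced by a quadratic penalty on the
    transformed scale.  Standard errors come from central-difference
    curvature of the objective at the optimum (covariance
    ``2 H^{-1}`` for a -2 log-likelihood); an RSE above 50% or a
    non-invertible curvature flags the parameter as non-identifiable.
    """
    names = list(spec.free)
    bounds = spec.resolved_bounds()
    z0 = np.array(
        [_to_internal(n, spec.free[n], *bounds[n]) for n in names]
    )
    z_lo = np.array(
        [_to_internal(n, bounds[n][0] * (1 + 1e-9), *bounds[n])
         if n == "imax_epo" else math.log(bounds[n][0]) for n in names]
    )
    z_hi = np.array(
        [_to_internal(n, bounds[n][1] * (1 - 1e-9), *bounds[n])
         if n == "imax_epo" else math.log(bounds[n][1]) for n in names]
    )

    n_evals = 0
    trace: list[float] = []

    def params_of(z: np.ndarray) -> PDParameterSet:
        vals = {
            n: _from_internal(n, float(zi), *bounds[n])
            for n, zi in zip(names, z)
        }
        return replace(spec.base, **vals)

    def penalized(z: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        pen = 0.0
        zc = np.clip(z, z_lo, z_hi)
        d = z - zc
        pen = 1e6 * float(d @ d)
        try:
            val = objective(params_of(zc), observations, predictor)
        except EstimationError:
            raise
        val = val + pen
        if not trace or val < trace[-1]:
            trace.append(val)
        return val

    rng = np.random.default_rng(seed)
    best = None
    converged = False
    for start in range(max(1, n_starts)):
        z_init = z0 if start == 0 else z0 + jitter_sd * rng.standard_normal(
            z0.size
        )
        z_init = np.clip(z_init, z_lo, z_hi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                penalized, z_init, method="Nelder-Mead",
                options={
                    "maxiter": maxiter * len(names),
                    "xatol": xatol, "fatol": fatol,
                },
            )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    z_hat = np.clip(best.x, z_lo, z_hi)
    estimates = {
        n: _from_internal(n, float(zi), *bounds[n])
        for n, zi in zip(names, z_hat)
    }
    theta = np.array([estimates[n] for n in names])

    def obj_nat(th: np.ndarray) -> float:
        p = replace(spec.base, **dict(zip(names, th)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return objective(p, observations, predictor)

    se, rse = _curvature_se(obj_nat, theta, names)
    non_ident = {
        n for n in names
        if not math.isfinite(rse[n]) or rse[n] > RSE_FLAG_PERCENT
    }
    result = FitResult(
        estimates=estimates,
        se=se,
        rse_percent=rse,
        objective_value=float(best.fun),
        converged=converged,
        non_identifiable=non_ident,
        n_evaluations=n_evals,
        trace=trace,
    )
    result.base_params = spec.base
    return result


def _curvature_se(obj, theta: np.ndarray, names: list[str], rel_step=1e-3):
    """Central-difference Hessian -> covariance ``2 H^{-1}`` -> SEs."""
    k = theta.size
    h = rel_step * np.abs(theta)
    f0 = obj(theta)
    hess = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        fpp = obj(theta + ei)
        fmm = obj(theta - ei)
        hess[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            fp_p = obj(theta + ei + ej)
            fp_m = obj(theta + ei - ej)
            fm_p = obj(theta - ei + ej)
            fm_m = obj(theta - ei - ej)
            hess[i, j] = hess[j, i] = (
                (fp_p - fp_m - fm_p + fm_m) / (4 * h[i] * h[j])
            )
    se = {}
    rse = {}
    try:
        cov = 2.0 * np.linalg.inv(hess)
        diag = np.diag(cov)
        for i, n in enumerate(names):
            if diag[i] <= 0 or not np.isfinite(diag[i]):
                se[n] = math.inf
            else:
                se[n] = float(math.sqrt(diag[i]))
    except np.linalg.LinAlgError:
        for n in names:
            se[n] = math.inf
    for i, n in enumerate(names):
        denom = abs(theta[i])
        rse[n] = (
            math.inf if not math.isfinite(se[n]) or denom == 0
            else 100.0 * se[n] / denom
        )
    return se, rse
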