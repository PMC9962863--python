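"""Synthetic data generation.

Everything the other modules consume can be generated here without any
external data: multi-species allometric tables drawn from a known power
law, and sparse PK/PD observation tables emulating a rat combination
study (monotherapy, combination and control arms) with proportional
lognormal residual error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import hematopoiesis as hp
from .allometry import SpeciesPoint
from .pk import EPO, ROMI, SC, DoseEvent, PKParameterSet, simulate_pk

__all__ = [
    "ANALYTES",
    "StudyDesign",
    "generate_species_table",
    "predict_study",
    "generate_study",
    "default_rat_study",
]

ANALYTES = ("EPO_conc", "ROMI_conc", "RBC", "PLT", "Hgb")

_DEFAULT_SPECIES = ("rat", "monkey", "human")


class SyntheticDataError(ValueError):
    pass


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def generate_species_table(
    a: float,
    b: float,
    body_weights: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    species: Sequence[str] | None = None,
) -> list[SpeciesPoint]:
    """Species points ``value = a * W^b * eps`` with lognormal noise.

    ``eps`` has median 1 and the given coefficient of variation, so the
    noiseless table lies exactly on the generating law.
    """
    if not (math.isfinite(a) and math.isfinite(b)):
        raise SyntheticDataError("a and b must be finite")
    if any(w <= 0 for w in body_weights):
        raise SyntheticDataError("body weights must be > 0")
    if noise_cv < 0:
        raise SyntheticDataError("noise_cv must be >= 0")
    if species is None:
        species = [
            _DEFAULT_SPECIES[i] if i < len(_DEFAULT_SPECIES) else f"sp{i}"
            for i in range(len(body_weights))
        ]
    rng = np.random.default_rng(seed)
    sigma = _lognormal_sigma(noise_cv)
    eps = np.exp(sigma * rng.standard_normal(len(body_weights)))
    return [
        SpeciesPoint(str(s), float(w), float(a * w**b * e))
        for s, w, e in zip(species, body_weights, eps)
    ]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of a synthetic PK/PD study.

    ``arms`` maps arm label to its dose events (an empty list is a
    control arm); ``sampling_times`` maps analyte name to sampling
    times in hours; ``residual_cv`` maps analyte to its proportional
    residual CV.  ``n_subjects`` pools that many independently noisy
    replicates of the sampling schedule per arm.
    """

    arms: Mapping[str, Sequence[DoseEvent]]
    sampling_times: Mapping[str, Sequence[float]]
    residual_cv: Mapping[str, float]
    horizon_h: float
    seed: int = 0
    n_subjects: int = 1
    grid_step_h: float = 1.0

    def __post_init__(self) -> None:
        for analyte in self.sampling_times:
            if analyte not in ANALYTES:
                raise SyntheticDataError(f"unknown analyte {analyte!r}")
            ts = np.asarray(self.sampling_times[analyte], dtype=float)
            if np.any(np.diff(ts) < 0):
                raise SyntheticDataError(
                    f"sampling times for {analyte!r} must be sorted"
                )
            if ts.size and ts[-1] > self.horizon_h:
                raise SyntheticDataError(
                    f"sampling time beyond horizon for {analyte!r}"
                )
        for analyte, cv in self.residual_cv.items():
            if cv < 0:
                raise SyntheticDataError(f"negative CV for {analyte!r}")
        if self.n_subjects < 1:
            raise SyntheticDataError("n_subjects must be >= 1")


def study_concentration_profiles(
    design: StudyDesign,
    pk_epo: PKParameterSet,
    pk_romi: PKParameterSet,
    plt_baseline: float,
):
    """Per-arm free-concentration profiles on the study grid.

    PK does not depend on the PD parameters (no feedback by default),
    so these can be computed once and reused across PD evaluations —
    the estimation module relies on this.
    """
    n = int(round(design.horizon_h / design.grid_step_h))
    grid = np.linspace(0.0, design.horizon_h, n + 1)
    out = {}
    for arm, events in design.arms.items():
        epo_prof = simulate_pk(pk_epo, events, grid)
        romi_prof = simulate_pk(
            pk_romi, events, grid, platelet_pool=plt_baseline
        )
        out[arm] = (epo_prof, romi_prof)
    return grid, out


def predict_study(
    design: StudyDesign,
    pk_epo: PKParameterSet,
    pk_romi: PKParameterSet,
    pd_params: hp.PDParameterSet,
    *,
    profiles=None,
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Noise-free model predictions at the design's sampling times.

    Returns a tidy frame (time_h, arm, analyte, value); rows are
    ordered by arm, then analyte, then time.
    """
    if profiles is None:
        grid, profiles = study_concentration_profiles(
            design, pk_epo, pk_romi, pd_params.plt0
        )
    baselines = hp.derive_baselines(pd_params)
    rows = []
    for arm in design.arms:
        epo_prof, romi_prof = profiles[arm]
        traj = hp.simulate_pd(
            pd_params, baselines, epo_prof, romi_prof, grid,
            rtol=rtol, atol=atol,
        )
        series = {
            "EPO_conc": (epo_prof.time, epo_prof.free_conc),
            "ROMI_conc": (romi_prof.time, romi_prof.free_conc),
            "RBC": (traj.time, traj.rbc),
            "PLT": (traj.time, traj.plt),
            "Hgb": (traj.time, traj.hgb),
        }
        for analyte, times in design.sampling_times.items():
            ts, vs = series[analyte]
            pred = np.interp(np.asarray(times, dtype=float), ts, vs)
            for t, v in zip(times, pred):
                rows.append(
                    {"time_h": float(t), "arm": arm, "analyte": analyte,
                     "value": float(v)}
                )
    return pd.DataFrame(rows, columns=["time_h", "arm", "analyte", "value"])


def generate_study(
    design: StudyDesign,
    pk_epo: PKParameterSet,
    pk_romi: PKParameterSet,
    pd_params: hp.PDParameterSet,
    **predict_kwargs,
) -> pd.DataFrame:
    """Noisy observation table for a synthetic study.

    Applies proportional lognormal error per analyte on top of
    :func:`predict_study`; reproducible under ``design.seed``.  Rows
    whose noise-free prediction is exactly zero (a drug concentration
    sampled in an arm that never receives that drug) are dropped, so
    every returned value is strictly positive.
    """
    pred = predict_study(design, pk_epo, pk_romi, pd_params, **predict_kwargs)
    pred = pred[pred["value"] > 0.0].reset_index(drop=True)
    rng = np.random.default_rng(design.seed)
    frames = []
    for subject in range(design.n_subjects):
        df = pred.copy()
        sigma = df["analyte"].map(
            {a: _lognormal_sigma(design.residual_cv.get(a, 0.0))
             for a in ANALYTES}
        ).to_numpy()
        eps = np.exp(sigma * rng.standard_normal(len(df)))
        df["value"] = df["value"].to_numpy() * eps
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def default_rat_study(
    seed: int = 0,
    *,
    n_subjects: int = 1,
    duration_weeks: int = 4,
    body_weight: float = 0.3,
    epo_dose_iu_per_kg: float = 450.0,
    romi_dose_ug_per_kg: float = 10.0,
) -> StudyDesign:
    """A compact four-arm rat study design (control / EPO / ROMI / combo).

    EPO thrice weekly, romiplostim once weekly, both SC, for
    ``duration_weeks``; hematology sampled every 3 days over the
    horizon (dosing + 2 weeks washout), drug concentrations on a sparse
    post-dose schedule.  Residual CVs default to 15% for concentrations
    and 7% for hematology.
    """
    horizon = (duration_weeks + 2) * 7 * 24.0
    epo_events = [
        DoseEvent((7 * w + off) * 24.0, EPO, SC, epo_dose_iu_per_kg,
                  body_weight)
        for w in range(duration_weeks) for off in (0, 2, 4)
    ]
    romi_events = [
        DoseEvent(7 * w * 24.0, ROMI, SC, romi_dose_ug_per_kg, body_weight)
        for w in range(duration_weeks)
    ]
    hema_times = list(np.arange(0.0, horizon + 1, 72.0))
    pk_times = [2.0, 8.0, 24.0, 48.0, 96.0, 168.0]
    return StudyDesign(
        arms={
            "control": [],
            "epo": epo_events,
            "romi": romi_events,
            "combo": epo_events + romi_events,
        },
        sampling_times={
            "EPO_conc": pk_times,
            "ROMI_conc": pk_times,
            "RBC": hema_times,
            "PLT": hema_times,
            "Hgb": hema_times,
        },
        residual_cv={
            "EPO_conc": 0.15, "ROMI_conc": 0.15,
            "RBC": 0.07, "PLT": 0.07, "Hgb": 0.07,
        },
        horizon_h=horizon,
        seed=seed,
        n_subjects=n_subjects,
    )
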