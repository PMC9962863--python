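"""Generate a synthetic rat study and re-estimate PD parameters.

Simulates a two-dose-level romiplostim study (10 and 1 ug/kg weekly,
platelets sampled every two days, 7% proportional noise, 8 pooled
subjects), then fits Smax_RM2, SC50_RM and T_MP back by maximum
likelihood and prints estimates with curvature-based RSEs.
"""

import dataclasses

import numpy as np

import hemoscale as hs
from hemoscale.estimation import FitSpec, StudyPredictor, fit
from hemoscale.pk import DoseEvent
from hemoscale.synthetic import StudyDesign, generate_study

rat_pk_epo, rat_pk_romi = hs.default_rat_pk()
rat_pd = hs.default_rat_pd()


def weekly(dose_ug_per_kg):
    return [DoseEvent(7 * w * 24.0, "ROMI", "SC", dose_ug_per_kg, 0.3)
            for w in range(2)]


times = list(np.arange(0.0, 504.1, 48.0))
design = StudyDesign(
    arms={"romi_high": weekly(10.0), "romi_low": weekly(1.0)},
    sampling_times={"PLT": times},
    residual_cv={"PLT": 0.07},
    horizon_h=504.0, seed=42, n_subjects=8, grid_step_h=4.0,
)
observations = generate_study(design, rat_pk_epo, rat_pk_romi, rat_pd)
print(f"synthetic study: {len(observations)} platelet observations, "
      "7% proportional noise")

predictor = StudyPredictor(design, rat_pk_epo, rat_pk_romi)
spec = FitSpec(
    base=rat_pd,
    free={
        "smax_rm2": rat_pd.smax_rm2 * 1.3,
        "sc50_rm": rat_pd.sc50_rm * 0.8,
        "t_mp": rat_pd.t_mp * 1.15,
    },
)
result = fit(spec, observations, predictor, n_starts=1, seed=0,
             maxiter=60, xatol=3e-4, fatol=1e-7)

print(f"{'parameter':<10} {'truth':>8} {'estimate':>9} {'RSE%':>6}")
for name in spec.free:
    truth = getattr(rat_pd, name)
    print(f"{name:<10} {truth:>8.3g} {result.estimates[name]:>9.4g} "
          f"{result.rse_percent[name]:>6.1f}")
print()
print("Estimates within a few percent of the generating values with")
print("small RSEs show the two-dose-level design identifies the")
print("romiplostim Emax/EC50 pair and the megakaryocyte lifespan.")
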