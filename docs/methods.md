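# Methods

This note records the model equations as implemented, the unit and
numerical conventions, the design choices made where the published
description left the structure open, and what the synthetic-data tests
do and do not demonstrate.

## States, units, conventions

Time is hours everywhere; day-denominated configuration entries
(`{value: 10.6, unit: day}`) are converted on load. rHuEPO amounts are
IU and concentrations IU/L (numerically identical to mIU/mL, the unit
of `SC50_EPO`/`IC50_EPO`); romiplostim amounts are µg and
concentrations ng/mL (= µg/L). Cell concentrations are carried in
units of 10¹² cells/L, so the platelet baseline is the number 0.23;
this keeps the 26-dimensional ODE state between ~10⁻³ and ~10¹ and
makes absolute solver tolerances meaningful. Hemoglobin is algebraic:
`Hgb [g/dL] = MCH [pg] · RBC [10¹²/L] / 10`.

## PK models

**Rat (Michaelis–Menten TMDD).** Depot → central → peripheral with
linear clearance plus a saturable elimination `V_M·C/(K_M+C)`. The
free concentration is the QE root with constant receptor pool
`R_tot = V_M/(V_c·k_int)` — the grouping is fixed by dimensional
analysis (IU/h divided by L·h⁻¹ gives IU/L). Rat parameter values are
synthetic fixtures (order-of-magnitude plausible, labelled as such in
`data/rat_pk_synthetic.yaml`); nothing downstream treats them as
literature estimates.

**Human rHuEPO (QE-TMDD with receptor turnover).** Two-compartment
disposition (`V2E`, `V3E`, `Q_E`, `CL_E`), first-order absorption, and
a dynamic receptor pool

    dR_tot/dt = k_deg·R_tot,0 − k_deg·R_tot − (k_int − k_deg)·RC,
    RC = R_tot·C/(K_M + C),

with the complex eliminated at `k_int`. Since the printed
`k_int (0.171/h) < k_deg (0.392/h)`, binding protects receptor and the
pool can rise above baseline under sustained dosing (toward
`k_deg·R_tot,0/k_int ≈ 355 IU/L`). The published source model's exact
reduction (QE vs QSS, separate complex state) is not recoverable; this
is the standard QE reduction consistent with the printed parameter
list.

**Human romiplostim.** Two-compartment linear disposition with
first-order absorption. The c-Mpl pool carried by platelets is
`r_tot [ng/mL] = ξ_R [fg/plt] · PLT [10¹²/L] · 10³` (≈ 4.95 ng/mL at
baseline). **By default this pool is *not* applied as a QE partition**:
the reported and PD-driving concentration is the total concentration.
Rationale: with `K_M = 0.131 ng/mL` the 4.95 ng/mL pool is a
near-stoichiometric sink, so free drug at a 1 µg/kg dose stays in the
picomolar range and a stimulus with `SC50 = 11.9 ng/mL` (estimated in
rats against measurable concentrations) could never engage — no
platelet response would be possible at label-range doses, contradicting
both observed single-dose responses in healthy subjects and the
published regimen behavior this package reproduces. Driving the Hill
functions on the total-concentration scale restores consistency (the
weekly 1 µg/kg regimen then crosses the platelet ceiling on day 11,
as published). The full QE partition, and dynamic coupling of the pool
to the simulated platelet count, remain available
(`receptor_partition=True`, `couple_platelet_pool=True` — the latter
uses fixed-point iteration between the PK and PD layers) for
sensitivity analyses.

Dosing is event-based: IV boluses add to the central amount, SC doses
add `F·dose` to the depot; integration restarts at every dose time so
discontinuities never straddle a solver step, and the concentration
reported at a dose time is the post-dose value.

## PD model

Layout `[MEP, BFU-E, CFU-E, NOR, RET, RBC, MK₁..₁₀, PLT₁..₁₀]`:

    dMEP/dt  = Kin1·S_R1 − (KE·S_E + KM)·MEP
    chain:     BFU-E → CFU-E → NOR, each with residence T_EP
    dRET/dt  = NOR/T_EP − (RET/T_RET)·I_E
    dRBC/dt  = (RET/T_RET)·I_E − RBC/T_RBC
    dMK₁/dt  = Kin2·S_R2 + KM·MEP − (10/T_MP)·MK₁   (cascade at 10/T_MP)
    dPLT₁/dt = (10/T_MP)·MK₁₀ − (10/T_PLT)·PLT₁     (cascade at 10/T_PLT)

with `S_x = 1 + Smax_x·C/(SC50_x + C)` and
`I_E = 1 − Imax·C/(IC50 + C)`; Hill coefficients are 1 throughout (no
exponents are printed). Effect placement: romiplostim expands MEP
production (`S_R1` on `Kin1`) and the MK-committed inflow (`S_R2` on
`Kin2`, sharing `SC50_RM`); EPO steers MEP fate by stimulating `KE`
and slows reticulocyte aging. This uses every printed effect parameter
exactly once and generates the depletion/competition phenomenology
(hemoglobin peak-then-decline under continued dosing, platelet
suppression below baseline).

Endogenous EPO and TPO are not modeled; the drug-free steady state
absorbs their effect, with baselines set to observed healthy values.
The erythroid chain has exactly the three named precursor stages and
no amplification factor — baseline closure makes one unidentifiable
from the printed constants, and the response amplitude is invariant to
it anyway (a gain G divides `MEP0` and multiplies the transit output by
G).

`T_EP` is the one constant not printed anywhere; the default is 48 h
(three stages ≈ 6 days of marrow transit, the right order for
erythroid precursor maturation). It is exposed in configuration; in
practice the simulated hemoglobin peak moves by under 0.1 g/dL across
24–72 h because the Hill stimulus is saturated at therapeutic
exposures.

## Known disagreement with the published simulation

With the printed constants and the structure above, rHuEPO 50 IU/kg IV
TIW yields a hemoglobin peak of ~17.3 g/dL near day 49 (published:
15.4 g/dL on day 64), and the week-2-start romiplostim regimens
overshoot the 0.35×10¹²/L platelet ceiling by 2–4%, so all eight
candidate regimens cross it (published: six). Both gaps are structural,
not tunable: the hemoglobin transient is fixed by
`MEP0 = (RBC0/T_RBC)/KE` and the saturated stimulus, and the maximum
EPO-induced platelet suppression is capped at
`KM·MEP0·T_PLT/PLT0 ≈ 29%` — all printed quantities. The package
reports what the stated constants compute rather than calibrating any
hidden factor; the weekly-romiplostim first-crossing day (11) and the
qualitative resistance/competition signatures are reproduced exactly.

## Numerics

LSODA throughout (the MM elimination near `K_M` is stiff), relative
tolerance 10⁻⁸ and absolute 10⁻¹⁰ for reported simulations; the PD
integrator caps steps at 24 h so pulsed forcing is never skipped.
Concentration forcing enters the PD system by linear interpolation on
the 1-h PK grid. The QE root uses the product (Citardauq) form of the
quadratic when `C_tot < R_tot + K_M`, which avoids the catastrophic
cancellation of the textbook root under receptor excess (residuals
stay below 10⁻¹⁰ relative across nine orders of magnitude); values in
(−10⁻¹², 0) from rounding are clamped to zero. Threshold crossings are
evaluated on a ≤ 1-h grid and reported as 1-based days
(`day = ceil(t/24)`, minimum 1). Fitting uses looser solver tolerances
(10⁻⁵/10⁻⁷, uncapped steps), which changes platelet predictions by
under 10⁻⁴ relative while tripling speed.

## Synthetic data and estimation

Observation tables carry proportional lognormal error (median-1,
CV-parameterized): 15% for drug concentrations, 7% for hematology —
conventional magnitudes for PK assays and cell counts. Baseline
variability in population simulations is lognormal with 10% CV on
`RBC0` and `PLT0` (median at the typical value), re-deriving the
steady-state closure per replicate; bands are pointwise 20th/50th/80th
percentiles (200 replicates by default).

Estimation is naive pooled maximum likelihood with the per-analyte
residual variance profiled out (`−2LL ∝ Σ_a n_a(log σ̂_a² + 1)`), a
log transform for positive parameters (logit for `Imax`), seeded
multi-start Nelder–Mead, and standard errors from central-difference
curvature (covariance `2H⁻¹`); RSE > 50% flags non-identifiability.
There is no random-effects layer — the published inter-individual
variability structure is not reprinted — so recovery studies speak to
the pooled design only. The default recovery design uses two
romiplostim dose levels (10 and 1 µg/kg weekly) so that concentrations
straddle `SC50_RM`: with a single high-dose arm the Emax/EC50 pair sits
on a likelihood ridge and recovery degrades — a genuine design
requirement, not a solver artifact. Under that design, noiseless data
return the generating parameters to ~10⁻⁵ relative, and 7% noise with
8 pooled subjects recovers all three free parameters within 20% (median
bias < 10%) across seeds.

What passing these tests shows: the estimator is consistent and the
design informative *for data generated by the model itself*. Real
studies add inter-animal variability, model misspecification, BLQ
censoring and dropout, none of which are emulated here.

## Limitations

Neocytolysis and stimulated early reticulocyte release are not
modeled; disease-state parameter shifts (shortened red-cell lifespan
in CKD) are out of scope; PK parameters are not scaled across species
(human PK is taken whole from published estimates); dose-titration
rules are not simulated. The romiplostim receptor-partition default
documented above is the package's resolution of an internal
inconsistency in the printed constants and should be revisited if the
source model's appendix equations become available.
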