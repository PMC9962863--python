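# Rat PD parameter set: healthy-rat lifespan/baseline estimates with the
# (species-conserved) effect parameters.  MCH is a synthetic fixture value:
# a rat MCH is not part of the printed constants.
T_MP: 47.8               # h
T_PLT: {value: 6.17, unit: day}
PLT0: 0.869              # 1e12 cells/L
T_RBC: {value: 60.8, unit: day}
T_RET: 20.0              # h
RBC0: 7.38               # 1e12 cells/L
KE: 6.84e-4
KM: 1.18e-4
Smax_RM1: 1.67
Smax_RM2: 27.8
Smax_EPO1: 11.3
SC50_RM: 11.9
SC50_EPO: 46.9
Imax_EPO: 0.422
IC50_EPO: 5.59
MCH: 20.0                # pg/cell (synthetic fixture)
T_EP: 48.0
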