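# Human PD parameter set for the scaled hematopoiesis model.
# Lifespans scaled from the rat; baselines and MCH fixed to human values;
# capacity/sensitivity parameters adopted from the rat unchanged.
T_MP: 137.1              # h, megakaryocyte lifespan (scaled)
T_PLT: 254.4             # h, platelet lifespan (scaled; 10.6 days)
PLT0: 0.23               # 1e12 cells/L
T_RBC: {value: 119.6, unit: day}
T_RET: 44.8              # h
RBC0: 4.4                # 1e12 cells/L
KE: 6.84e-4              # 1/h, MEP -> BFU-E differentiation
KM: 1.18e-4              # 1/h, MEP -> MK1 differentiation
Smax_RM1: 1.67           # romiplostim on MEP production
Smax_RM2: 27.8           # romiplostim on MK-committed pathway
Smax_EPO1: 11.3          # rHuEPO on MEP erythroid commitment
SC50_RM: 11.9            # ng/mL
SC50_EPO: 46.9           # mIU/mL
Imax_EPO: 0.422          # rHuEPO on RET aging rate
IC50_EPO: 5.59           # mIU/mL
MCH: 30.2                # pg/cell
T_EP: 48.0               # h, per-stage erythroid precursor residence
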