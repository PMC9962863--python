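# Human PK parameter sets (quasi-equilibrium TMDD), symbol-keyed.
# rHuEPO concentrations in IU/L (= mIU/mL); romiplostim in ng/mL.
epo:
  CL_E: 0.379      # L/h
  KA_E: 0.0269     # 1/h
  F_E: 0.513       # fraction
  V2E: 3.25        # L
  V3E: 1.64        # L
  Q_E: 0.0993      # L/h
  RTOT0: 154.7     # IU/L, baseline total EPO receptor
  KM_E: 48.1       # IU/L
  KINT_E: 0.171    # 1/h
  KDEG_E: 0.392    # 1/h
romi:
  CL_R: 0.183      # L/h
  V2R: 4.781       # L
  KCPR: 0.0806     # 1/h
  KPCR: 0.0148     # 1/h
  KA_RM: 0.0254    # 1/h
  F_RM: 0.499      # fraction
  KM_R: 0.131      # ng/mL
  XI_R: 0.0215     # fg c-Mpl receptor per platelet
  KINT_R: 0.173    # 1/h
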