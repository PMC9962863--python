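# SYNTHETIC rat PK fixtures (Michaelis-Menten TMDD parameterization).
# These are order-of-magnitude plausible values used to exercise the rat
# model and to generate synthetic studies; they are not literature
# estimates.
epo:
  KA_E: 0.25       # 1/h
  F_E: 0.7
  CL_EPO: 0.004    # L/h
  V_CEPO: 0.013    # L
  V_MEPO: 5.0      # IU/h
  K_MEPO: 120.0    # IU/L
  K_CPEPO: 0.1     # 1/h
  K_PCEPO: 0.15    # 1/h
  K_INTE: 0.3      # 1/h
romi:
  KA_RM: 0.15      # 1/h
  F_RM: 0.55
  CL_RM: 0.0025    # L/h
  V_CRM: 0.012     # L
  V_MRM: 0.02      # ug/h
  K_MRM: 10.0      # ng/mL
  K_CPRM: 0.08     # 1/h
  K_PCRM: 0.1      # 1/h
  K_INTR: 0.25     # 1/h
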