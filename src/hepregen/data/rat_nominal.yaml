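# Nominal rat parameter set (values as published; G_rate in doublings/min)
M: 20.8
G_rate: 0.00035
k_IL6: 1.5
kappa_IL6: 0.9
V_JAK: 20000.0
Km_JAK: 10000.0
kappa_JAK: 0.4
pro_STAT3: 2.0
V_STAT3: 750.0
Km_STAT3: 0.4
kappa_STAT3: 0.1
V_SOCS3: 24000.0
Km_SOCS3: 0.0007
kappa_SOCS3: 0.4
KI_SOCS3: 0.015
V_IE: 250.0
Km_IE: 18.0
kappa_IE: 5.0
kappa_deg: 7.0
kappa_ECM: 33.0
k_GF: 0.113
kappa_GF: 0.23
k_up: 0.06
k_QP: 0.007
k_PR: 0.0044
k_RQ: 0.0054
k_prol: 0.02
k_req: 0.1
theta_req: 8.0
beta_req: 3.0
k_ap: 0.1
theta_ap: 0.009
beta_ap: 0.0045
k_MBF: 1.0
kappa_MBF: 1.0
phx_fraction: 0.7
IE0: 1.0
GF0: 1.0
ECM0: 1.0
MBF_ECM0: 50.0
include_growth: true
include_mbf: false
apoptosis_convention: inverse_demand
apoptosis_load_scale: 0.84
demand_convention: whole_liver
requiescence_on_replicating: true
apoptosis_p_convention: P
growth_lag_h: 10.0
growth_gate_width: 0.1
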