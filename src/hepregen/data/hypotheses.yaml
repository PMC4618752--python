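# Alternative hypotheses for human regeneration: parameter overrides
1:
  description: altered cytokine response
  overrides:
    KI_SOCS3: 0.0569
    Km_IE: 88.13
    Km_JAK: 7565.0
    Km_STAT3: 0.5178
    V_IE: 18.6
    V_JAK: 1364.0
    V_STAT3: 1109.0
    k_IL6: 0.1435
    kappa_IE: 1.148
    kappa_IL6: 0.4942
    kappa_JAK: 0.0398
    kappa_SOCS3: 0.1682
    pro_STAT3: 2.031
2:
  description: altered GF storage and ECM balance
  overrides:
    k_GF: 0.003288
    k_up: 0.1008
    kappa_ECM: 56.3
    kappa_GF: 0.002139
    kappa_deg: 4.955
3:
  description: altered state-transition rates
  overrides:
    k_PR: 0.0015
    k_QP: 0.0014
    k_RQ: 0.0709
4:
  description: slower cell cycle, apoptosis and requiescence with altered transitions
  overrides:
    k_PR: 0.0026
    k_QP: 0.0011
    k_RQ: 0.135
    k_ap: 0.00417
    k_prol: 0.00833
    k_req: 0.00417
5:
  description: reduced metabolic demand
  overrides:
    G_rate: 0.0003474
    M: 20.8217
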