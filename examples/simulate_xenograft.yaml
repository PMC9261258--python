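# One growth-model simulation: EGFR-exon-19-deletion xenograft under gefitinib.
# Run with:  stepcal simulate --config examples/simulate_xenograft.yaml
parameters:
  k_div: 0.2
  k_q: 0.7
  k_n: 0.4
  k_lys: 0.05
  L_p: 60.0
  L_v: 250.0
  k_ang: 0.3
  d_ang: 0.1
  a_ang: 10.0
  e_imm: 0.02
  k_kill: 0.5
  c_gef: 50.0
scenario:
  mode: xenograft
  dosing: gefitinib
  horizon_days: 30.0
  mutations: {egfr_ex19del: true}
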