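# Calibrated default parameters for the five-state
# (LT-HSC/ST-HSC/MPP/CMP/Terminal) model.  Proliferation and secretion rates
# are constants in this variant.  Units as in the three-state file.
kind: five_state
params:
  PR_LT: 0.4
  PR_ST: 1.0
  PR_MPP: 0.9
  PR_CMP: 0.6
  PR_Term: 0.63
  DR_max_LT: 0.2
  DR_max_ST: 0.3
  DR_max_MPP: 0.3
  DR_max_CMP: 0.3
  DR_max_Term: 0.25
  d_LT: 1.0
  d_ST: 1.0
  d_MPP: 1.0
  d_CMP: 1.0
  d_Term: 1.0
  f_max_LT: 0.5
  f_max_ST: 0.9
  f_max_MPP: 0.95
  f_max_CMP: 0.7
  s_LT: 0.01
  s_ST: 0.02
  s_MPP: 0.02
  s_CMP: 0.02
  q_max_LT: 0.7
  q_max_ST: 0.2
  q_max_MPP: 0.1
  j_max_STtoTerm: 0.7
  j_max_MPPtoTerm: 0.7
  DR_LTtoST: 1.0
  DR_STtoMPP: 0.6
  DR_MPPtoCMP: 0.8
  DR_CMPtoTerm: 3.0
  DR_STtoTerm: 1.3
  DR_MPPtoTerm: 1.8
  c_prog_DiffS: 1.2e-4
  c_prog_DiffI: 1.0e-4
  c_prog_ProS: 2.0e-4
  c_prog_ProI: 1.0e-4
  c_term_DiffS: 1.0e-5
  c_term_DiffI: 2.0e-4
  c_term_ProS: 1.0e-4
  c_term_ProI: 1.0e-4
  K_SCF_consumption: 5.0e-5
  K_GC_consumption: 2.0e-6
  c_hat: 1.0
  s_hat: 1.0
  t_hat: 1.0
  td_mode: terminal_product
  quiescence_gates_death: false
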