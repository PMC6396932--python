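# Calibrated default parameters for the three-state (LSK/CMP/Terminal) model.
# Units: rates 1/day; d_* 1/mM; s_* mL/ng; secretion m_* ng/cell/day;
# K_SCF_consumption ng/cell/day; K_GC_consumption mM/cell/day.
kind: three_state
params:
  PR_max_LSK: 1.0
  PR_max_CMP: 0.6
  PR_max_Term: 0.58
  DR_max_LSK: 0.3
  DR_max_CMP: 0.3
  DR_max_Term: 0.25
  d_LSK: 1.0
  d_CMP: 1.0
  d_Term: 1.0
  f_max_LSK: 0.85
  f_max_CMP: 0.7
  s_LSK: 0.005
  s_CMP: 0.02
  q_max: 0.3
  j_max: 0.7
  DR_LSKtoCMP: 0.3
  DR_LSKtoTerm: 2.6
  DR_CMPtoTerm: 3.0
  m_prog_DiffS: 6.0e-4
  m_prog_DiffI: 1.0e-4
  m_prog_ProS: 2.0e-4
  m_prog_ProI: 1.0e-4
  m_term_DiffS: 3.0e-5
  m_term_DiffI: 4.0e-4
  m_term_ProS: 1.0e-4
  m_term_ProI: 1.0e-4
  K_SCF_consumption: 5.0e-5
  K_GC_consumption: 2.0e-6
  c_hat: 1.0
  s_hat: 1.0
  t_hat: 1.0
  td_mode: terminal_product
  quiescence_gates_death: false
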