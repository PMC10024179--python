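{
  "genome_instability_and_mutation": {
    "parameters": ["p_mutation"],
    "rationale": "Mutational processes drive the finite-allele antigen turnover of cancer cells."
  },
  "epithelial_mesenchymal_transition": {
    "parameters": ["p_migration_cancer"],
    "rationale": "EMT programs increase cancer cell motility."
  },
  "e2f_targets": {
    "parameters": ["t_proliferation"],
    "rationale": "E2F target activation marks cell-cycle progression speed."
  },
  "g2m_checkpoint": {
    "parameters": ["t_proliferation"],
    "rationale": "G2/M checkpoint activity reflects cell-cycle duration."
  },
  "mitotic_spindle": {
    "parameters": ["t_proliferation"],
    "rationale": "Mitotic machinery expression tracks division rate."
  },
  "tgf_beta_signaling": {
    "parameters": ["tau_sup"],
    "rationale": "TGF-beta is a canonical immunosuppressive cytokine; maps to the SUP coupling."
  },
  "inflammatory_response": {
    "parameters": ["r_ctl"],
    "rationale": "Inflammatory signaling recruits cytotoxic lymphocytes."
  },
  "il2_stat5_signaling": {
    "parameters": ["r_ctl"],
    "rationale": "IL2/STAT5 drives T cell expansion and recruitment."
  },
  "interferon_gamma_response": {
    "parameters": ["tau_enh"],
    "rationale": "IFN-gamma boosts cytotoxic effectiveness; maps to the ENH coupling."
  },
  "interferon_alpha_response": {
    "parameters": ["tau_enh"],
    "rationale": "Type-I interferon enhances the cytotoxic response."
  }
}
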