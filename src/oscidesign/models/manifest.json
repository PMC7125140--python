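{
  "schema_version": 1,
  "designs": {
    "1A": {"file": "design_1A.txt", "k_parameter": null,
           "species": {"Sic1": "s", "Clb5": "x", "Clb3": "y", "Clb2": "z"},
           "description": "Mass-action core: documented interactions only, lumped Cln-mediated Sic1 degradation (k_cln); no Clb PFLs or self-NFLs."},
    "1B": {"file": "design_1B.txt", "k_parameter": null,
           "species": {"Sic1": "s", "Clb5": "x", "Clb3": "y", "Clb2": "z"},
           "description": "1A plus the hypothetical Clb3/Clb2 positive feedback loops (alpha_yy, alpha_zz)."},
    "1C": {"file": "design_1C.txt", "k_parameter": null,
           "species": {"Sic1": "s", "Clb5": "x", "Clb3": "y", "Clb2": "z"},
           "description": "1B plus the APC-mediated Clb3/Clb2 self negative feedback loops (gamma_yy, gamma_zz)."},
    "2":  {"file": "design_2.txt", "k_parameter": null,
           "species": {"Sic1": "s", "Clb5": "x", "Clb3": "y", "Clb2": "z"},
           "description": "Full interaction set with explicit ternary-complex kinetics; mass-action counterpart of design 3."},
    "3":  {"file": "design_3.txt", "k_parameter": null,
           "species": {"Sic1": "s", "Clb5": "x", "Clb3": "y", "Clb2": "z"},
           "description": "QSSA core: ternary complexes at binding equilibrium via K_A."},
    "4":  {"file": "design_4.txt", "k_parameter": "K_zx",
           "species": {"Sic1": "s", "Clb5": "x", "Clb3": "y", "Clb2": "z"},
           "description": "Design 3 + transcriptional inhibition of Clb5 synthesis by Clb2/Cdk1."},
    "5":  {"file": "design_5.txt", "k_parameter": "K_zs",
           "species": {"Sic1": "s", "Clb5": "x", "Clb3": "y", "Clb2": "z"},
           "description": "Design 3 + transcriptional inhibition of Sic1 synthesis by Clb2/Cdk1."},
    "6":  {"file": "design_6.txt", "k_parameter": "K_cs",
           "species": {"Sic1": "s", "Clb5": "x", "Clb3": "y", "Clb2": "z"},
           "description": "Design 3 + inhibition of Sic1 synthesis by all three Clb/Cdk1 complexes."},
    "7":  {"file": "design_7.txt", "k_parameter": "K_sm",
           "species": {"Sic1": "s", "Clb5": "x", "Clb3": "y", "Clb2": "z"},
           "description": "Design 3 + hypothetical inhibition of Clb3 and Clb2 synthesis by Sic1."},
    "8":  {"file": "design_8.txt", "k_parameter": "K_sc",
           "species": {"Sic1": "s", "Clb5": "x", "Clb3": "y", "Clb2": "z"},
           "description": "Design 3 + hypothetical inhibition of Clb5, Clb3 and Clb2 synthesis by Sic1."},
    "9":  {"file": "design_9.txt", "k_parameter": "K_ss",
           "species": {"Sic1": "s", "Clb5": "x", "Clb3": "y", "Clb2": "z"},
           "description": "Design 3 + hypothetical inhibition of Sic1 synthesis by Sic1 itself."}
  }
}
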