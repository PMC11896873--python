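{
  "description": "Default 12-transporter registry: 24 (target, mode) models. Approach is 'gcnn' where enough public bioactivity data support a trained network and 'similarity' elsewhere. Artifact paths are null until models are trained or reference sets supplied locally.",
  "targets": [
    {"target_name": "Pgp", "gene_symbol": "ABCB1", "mode": "inhibitor", "approach": "gcnn", "model_path": null},
    {"target_name": "Pgp", "gene_symbol": "ABCB1", "mode": "substrate", "approach": "gcnn", "model_path": null},
    {"target_name": "BCRP", "gene_symbol": "ABCG2", "mode": "inhibitor", "approach": "gcnn", "model_path": null},
    {"target_name": "BCRP", "gene_symbol": "ABCG2", "mode": "substrate", "approach": "gcnn", "model_path": null},
    {"target_name": "MRP1", "gene_symbol": "ABCC1", "mode": "inhibitor", "approach": "gcnn", "model_path": null},
    {"target_name": "MRP1", "gene_symbol": "ABCC1", "mode": "substrate", "approach": "gcnn", "model_path": null},
    {"target_name": "BSEP", "gene_symbol": "ABCB11", "mode": "inhibitor", "approach": "gcnn", "model_path": null},
    {"target_name": "BSEP", "gene_symbol": "ABCB11", "mode": "substrate", "approach": "similarity", "reference_set_path": null},
    {"target_name": "MRP2", "gene_symbol": "ABCC2", "mode": "inhibitor", "approach": "similarity", "reference_set_path": null},
    {"target_name": "MRP2", "gene_symbol": "ABCC2", "mode": "substrate", "approach": "similarity", "reference_set_path": null},
    {"target_name": "OATP1B1", "gene_symbol": "SLCO1B1", "mode": "inhibitor", "approach": "gcnn", "model_path": null},
    {"target_name": "OATP1B1", "gene_symbol": "SLCO1B1", "mode": "substrate", "approach": "similarity", "reference_set_path": null},
    {"target_name": "OATP1B3", "gene_symbol": "SLCO1B3", "mode": "inhibitor", "approach": "gcnn", "model_path": null},
    {"target_name": "OATP1B3", "gene_symbol": "SLCO1B3", "mode": "substrate", "approach": "similarity", "reference_set_path": null},
    {"target_name": "OAT1", "gene_symbol": "SLC22A6", "mode": "inhibitor", "approach": "similarity", "reference_set_path": null},
    {"target_name": "OAT1", "gene_symbol": "SLC22A6", "mode": "substrate", "approach": "similarity", "reference_set_path": null},
    {"target_name": "OAT3", "gene_symbol": "SLC22A8", "mode": "inhibitor", "approach": "similarity", "reference_set_path": null},
    {"target_name": "OAT3", "gene_symbol": "SLC22A8", "mode": "substrate", "approach": "similarity", "reference_set_path": null},
    {"target_name": "OCT2", "gene_symbol": "SLC22A2", "mode": "inhibitor", "approach": "similarity", "reference_set_path": null},
    {"target_name": "OCT2", "gene_symbol": "SLC22A2", "mode": "substrate", "approach": "similarity", "reference_set_path": null},
    {"target_name": "MATE-1", "gene_symbol": "SLC47A1", "mode": "inhibitor", "approach": "similarity", "reference_set_path": null},
    {"target_name": "MATE-1", "gene_symbol": "SLC47A1", "mode": "substrate", "approach": "similarity", "reference_set_path": null},
    {"target_name": "MATE-2K", "gene_symbol": "SLC47A2", "mode": "inhibitor", "approach": "similarity", "reference_set_path": null},
    {"target_name": "MATE-2K", "gene_symbol": "SLC47A2", "mode": "substrate", "approach": "similarity", "reference_set_path": null}
  ]
}
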