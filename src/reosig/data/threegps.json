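{
 "pairs": [
  {"gene_a": "ORC1", "gene_b": "OLR1", "high_risk_reo": "a<b", "cox_p": null, "cox_hr": null},
  {"gene_a": "MTNR1A", "gene_b": "VGLL1", "high_risk_reo": "a<b", "cox_p": null, "cox_hr": null},
  {"gene_a": "RFX5", "gene_b": "MMP14", "high_risk_reo": "a<b", "cox_p": null, "cox_hr": null}
 ],
 "vote_threshold": 2
}
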