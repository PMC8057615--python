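{
 "labels": [
  "CSF1_mrna",
  "STAT1_mrna",
  "STAT3_mrna",
  "IRF8_mrna",
  "PU1_mrna",
  "NFKB_mrna",
  "CEBPA_mrna",
  "IL6R_mrna",
  "TNFR1_mrna",
  "CSF1R_mrna",
  "CSF3R_mrna",
  "STAT1_prot_inactive",
  "STAT1_prot_active",
  "STAT3_prot_inactive",
  "STAT3_prot_active",
  "NFKB_prot_inactive",
  "NFKB_prot_active",
  "CEBPA_prot_inactive",
  "CEBPA_prot_active",
  "CSF1R_prot_inactive",
  "CSF1R_prot_active"
 ],
 "state": [
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  2926.039192973685,
  73.96080702631497,
  2773.0264463784156,
  226.97355362158427,
  2857.1683627923585,
  142.8316372076415,
  2337.465270356914,
  662.534729643086,
  2381.0444874274663,
  618.9555125725338
 ],
 "note": "basal (unstimulated) steady state, lps = 0"
}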