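{
  "_comment": "Template for ingesting the original study's per-patient raw table. Place that table at data/s3_table1_raw.csv and edit the values below to the source file's actual headers (key = canonical lungheq field, value = source header). Entries whose header already matches the canonical name may be deleted.",
  "column_map": {
    "patient_id": "patient_id",
    "age": "age",
    "sex": "sex",
    "brinkman_index": "brinkman_index",
    "malignant_tumor_history": "malignant_tumor_history",
    "outcome": "outcome",
    "lung_area": "lung_area",
    "laa_pct_950": "laa_pct_950",
    "laa_pct_910": "laa_pct_910",
    "laa_pct_880": "laa_pct_880",
    "b0_950": "b0_950",
    "b0_910": "b0_910",
    "b0_880": "b0_880",
    "b1_950": "b1_950",
    "b1_910": "b1_910",
    "b1_880": "b1_880"
  }
}
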