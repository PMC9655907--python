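{
  "schema_version": 1,
  "standards": {
    "ASTM_D6751": {
      "kv": {"lower": 1.9, "upper": 6.0},
      "cn": {"lower": 47},
      "density": {"lower": 0.85, "upper": 0.90},
      "cp": {"lower": 4, "lower_open": true},
      "c18_3_pct": {"upper": 12}
    },
    "EN_14214": {
      "kv": {"lower": 3.5, "upper": 5.0},
      "cn": {"lower": 51},
      "iv": {"upper": 120},
      "density": {"lower": 0.86, "upper": 0.90},
      "db4plus_pct": {"upper": 10},
      "c18_3_pct": {"upper": 12}
    }
  }
}
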