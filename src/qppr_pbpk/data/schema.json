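{
  "partition_coefficients.csv": {
    "key": "name",
    "columns": {
      "name": {"type": "string", "description": "canonical chemical slug (lowercase, locant-prefixed)"},
      "dataset": {"type": "string", "enum": ["calibration", "evaluation"]},
      "pba": {"type": "number", "unit": "dimensionless", "description": "rat blood:air partition coefficient", "minimum_exclusive": 0},
      "p_liver_blood": {"type": "number", "unit": "dimensionless", "minimum_exclusive": 0},
      "p_rich_blood": {"type": "number", "unit": "dimensionless", "minimum_exclusive": 0},
      "p_poor_blood": {"type": "number", "unit": "dimensionless", "minimum_exclusive": 0},
      "p_fat_blood": {"type": "number", "unit": "dimensionless", "minimum_exclusive": 0},
      "p_pl_blood": {"type": "number", "unit": "dimensionless", "description": "phospholipid:blood partition coefficient", "minimum_exclusive": 0}
    }
  },
  "clearance_descriptors.csv": {
    "key": "name",
    "columns": {
      "name": {"type": "string"},
      "dataset": {"type": "string", "enum": ["calibration", "evaluation"]},
      "log_pow": {"type": "number", "unit": "log10 dimensionless"},
      "log_pbw": {"type": "number", "unit": "log10 dimensionless"},
      "ip": {"type": "number", "unit": "eV", "description": "calculated ionization potential"},
      "log_clint_pl_exp": {"type": "number", "unit": "log10(L PL/h/kg^0.75)"}
    }
  },
  "auxiliary_properties.csv": {
    "key": "name",
    "columns": {
      "name": {"type": "string"},
      "mw": {"type": "number", "unit": "g/mol", "minimum_exclusive": 0},
      "kf": {"type": "number", "unit": "1/h", "minimum": 0}
    }
  }
}
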