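{
  "type": "object",
  "required": ["manifest", "descriptive", "inference"],
  "properties": {
    "manifest": {
      "type": "object",
      "required": ["config_hash", "master_seed", "package_version"],
      "properties": {
        "config_hash": {"type": "string"},
        "master_seed": {"type": "number"},
        "package_version": {"type": "string"}
      }
    },
    "descriptive": {
      "type": "object",
      "required": ["gamma_fit_reference", "gamma_fit_regulated",
                   "cv_ratio", "fold_change"],
      "properties": {
        "gamma_fit_reference": {
          "type": "object",
          "required": ["shape", "scale", "cv", "mean", "n"],
          "properties": {
            "shape": {"type": "number"}, "scale": {"type": "number"},
            "cv": {"type": "number"}, "mean": {"type": "number"},
            "n": {"type": "number"}
          }
        },
        "gamma_fit_regulated": {
          "type": "object",
          "required": ["shape", "scale", "cv", "mean", "n"],
          "properties": {
            "shape": {"type": "number"}, "scale": {"type": "number"},
            "cv": {"type": "number"}, "mean": {"type": "number"},
            "n": {"type": "number"}
          }
        },
        "cv_ratio": {"type": "number"},
        "cv_ratio_outliers_excluded": {"type": "number"},
        "fold_change": {"type": "number"},
        "relative_mrna": {"type": "object"}
      }
    },
    "inference": {
      "type": "object",
      "required": ["runs"],
      "properties": {
        "runs": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["mu", "evidence_trajectory", "final_evidence",
                         "iterations_completed"],
            "properties": {
              "mu": {"type": "number"},
              "iterations_completed": {"type": "number"},
              "evidence_trajectory": {"type": "array"},
              "final_evidence": {"type": "object"},
              "posterior_summary": {"type": "object"},
              "best_model": {"type": "string"}
            }
          }
        }
      }
    }
  }
}
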