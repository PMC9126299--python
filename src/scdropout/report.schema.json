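{
  "type": "object",
  "required": ["seed", "config_hash", "version", "qc", "degs",
               "degs_per_cluster", "coverage", "coverage_significant_degs",
               "tf_detection", "overlap", "composition", "pca"],
  "properties": {
    "seed": {"type": "integer"},
    "config_hash": {"type": "string"},
    "version": {"type": "string"},
    "qc": {"type": "object"},
    "degs": {"type": "object"},
    "degs_per_cluster": {"type": "object"},
    "coverage": {
      "type": "object",
      "required": ["reference", "filter_limit", "datasets"],
      "properties": {
        "reference": {"type": "string"},
        "filter_limit": {"type": "number"},
        "datasets": {"type": "object"}
      }
    },
    "coverage_significant_degs": {"type": "object"},
    "tf_detection": {
      "type": "object",
      "required": ["detected", "significant_degs"]
    },
    "overlap": {
      "type": "object",
      "required": ["TPxCP_vs_TBxCB"]
    },
    "composition": {
      "type": "object",
      "required": ["proportions", "representation_reduction_percent",
                   "proportional_dropout", "flagged_types"]
    },
    "pca": {
      "type": "object",
      "required": ["variance_explained", "pc1_method_silhouette"]
    }
  }
}
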