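{
  "rat": {
    "required": {
      "n_mirnas_input": "int",
      "n_mirnas_expressed": "int",
      "n_de_diet": "int",
      "n_de_diet_up": "int",
      "n_de_diet_down": "int",
      "n_de_treatment": "int",
      "n_clusters": "int",
      "n_de_in_clusters": "int",
      "n_coexpressed_clusters": "int",
      "coexpressed_cluster_ids": "list",
      "enrichment": "dict",
      "correlation_thresholds": "dict",
      "parameters": "dict",
      "seed": "int"
    },
    "enrichment_required": {"k": "int", "K": "int", "n": "int", "N": "int", "odds_ratio": "float", "p_value": "float"}
  },
  "qpcr": {
    "required": {
      "n_targets": "int",
      "n_samples": "int",
      "groups": "list",
      "n_significant_targets": "int",
      "n_pairs": "int",
      "n_significant_pairs": "int",
      "parameters": "dict",
      "seed": "int"
    }
  }
}
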