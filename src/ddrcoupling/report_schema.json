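{
  "type": "object",
  "required": [
    "provenance",
    "hub_summaries",
    "divergence_ratios",
    "trajectories",
    "differential_expression",
    "category_summary",
    "classifier",
    "attribution",
    "convergence"
  ],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["config_hash", "seed", "package_version"],
      "properties": {
        "config_hash": {"type": "string"},
        "seed": {"type": "integer"},
        "package_version": {"type": "string"}
      }
    },
    "hub_summaries": {"type": "object"},
    "divergence_ratios": {"type": "object"},
    "trajectories": {"type": "array"},
    "differential_expression": {"type": "array"},
    "category_summary": {"type": "object"},
    "classifier": {
      "type": "object",
      "required": ["accuracy", "auc", "recall", "confusion"]
    },
    "attribution": {
      "type": "object",
      "required": ["gene_importance", "interaction_importance"]
    },
    "convergence": {
      "type": "object",
      "required": [
        "top_delta_pair",
        "top_fold_gene",
        "top_interaction_pair",
        "converged"
      ]
    }
  }
}
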