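{
  "type": "object",
  "required": ["version", "seed", "config", "stages"],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "stages": {
      "type": "object",
      "properties": {
        "quantify": {
          "type": "object",
          "required": ["n_proteins", "detected_sizes"]
        },
        "differential": {
          "type": "object",
          "required": ["n_enriched", "n_reduced", "n_total_differential"]
        },
        "annotate": {
          "type": "object",
          "required": ["category_difference", "enrichment"]
        },
        "coloc": {
          "type": "object",
          "required": ["n_rois", "pooled_m1", "pooled_m2"]
        },
        "ci": {
          "type": "object",
          "required": ["fa_levels", "ci_mean", "apoptosis_fraction"]
        }
      }
    }
  }
}
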