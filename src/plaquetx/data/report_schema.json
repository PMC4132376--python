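{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "plaquetx pipeline report",
  "type": "object",
  "required": [
    "seed",
    "n_subjects",
    "n_pairs",
    "n_transcripts",
    "n_species",
    "size_factors",
    "core",
    "linkage",
    "network",
    "functional"
  ],
  "properties": {
    "seed": {"type": "integer"},
    "n_subjects": {"type": "integer"},
    "n_pairs": {"type": "integer"},
    "n_transcripts": {"type": "integer"},
    "n_species": {"type": "integer"},
    "size_factors": {"type": "object"},
    "core": {
      "type": "object",
      "required": ["level", "min_count", "n_core", "taxa"],
      "properties": {
        "level": {"type": "string"},
        "min_count": {"type": "integer"},
        "n_core": {"type": "integer"},
        "taxa": {"type": "array"}
      }
    },
    "linkage": {
      "type": "object",
      "required": ["metric", "method", "linked_def", "strata"],
      "properties": {
        "metric": {"type": "string"},
        "method": {"type": "string"},
        "linked_def": {"type": "string"},
        "strata": {"type": "object"},
        "p_value": {"type": "number"},
        "n_perm": {"type": "integer"}
      }
    },
    "network": {
      "type": "object",
      "required": ["level", "min_abs_rho", "n_edges", "n_complexes", "complexes"],
      "properties": {
        "level": {"type": "string"},
        "min_abs_rho": {"type": "number"},
        "n_edges": {"type": "integer"},
        "n_complexes": {"type": "integer"},
        "complexes": {"type": "array"}
      }
    },
    "functional": {
      "type": "object",
      "required": ["denominator", "top_categories"],
      "properties": {
        "denominator": {"type": "string"},
        "top_categories": {"type": "object"}
      }
    }
  }
}
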