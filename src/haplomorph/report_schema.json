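{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "haplomorph pipeline report",
  "type": "object",
  "required": ["provenance", "data", "delimitation", "morphospace", "warnings"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["version", "seed", "config_hash"],
      "properties": {
        "version": {"type": "string"},
        "seed": {"type": "integer"},
        "config_hash": {"type": "string"}
      }
    },
    "data": {
      "type": "object",
      "required": ["n_sequences", "alignment_length", "n_individuals"],
      "properties": {
        "n_sequences": {"type": "integer", "minimum": 2},
        "alignment_length": {"type": "integer", "minimum": 1},
        "n_individuals": {"type": "integer", "minimum": 1}
      }
    },
    "distances": {
      "type": "object",
      "required": ["units", "gdmin_pct", "band", "conservative_species_count"],
      "properties": {
        "units": {"type": "array", "items": {"type": "string"}},
        "conservative_species_count": {"type": "integer", "minimum": 1}
      }
    },
    "delimitation": {
      "type": "object",
      "required": ["ffr_count", "abgd_group_counts", "abgd_range"],
      "properties": {
        "ffr_count": {"type": "integer", "minimum": 1},
        "abgd_range": {
          "type": "array",
          "items": {"type": "integer"},
          "minItems": 2,
          "maxItems": 2
        },
        "gmyc": {
          "type": "object",
          "required": ["n_entities", "LR", "p_value"],
          "properties": {
            "n_entities": {"type": "integer", "minimum": 1},
            "LR": {"type": "number", "minimum": 0},
            "p_value": {"type": "number", "minimum": 0, "maximum": 1}
          }
        }
      }
    },
    "integration": {
      "type": "object",
      "required": ["variance_share_1_2", "n_subclusters", "subclusters"]
    },
    "morphospace": {"type": "object"},
    "warnings": {"type": "array", "items": {"type": "string"}}
  }
}
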