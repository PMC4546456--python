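{
  "type": "object",
  "required": ["version", "config", "patients", "labels", "activation",
               "group_summaries", "triplets", "menu"],
  "properties": {
    "version": {"type": "string"},
    "config": {"type": "object"},
    "patients": {"type": "array", "items": {"type": "string"}},
    "labels": {"type": "array", "items": {"type": "string"}},
    "activation": {
      "type": "object",
      "description": "patient id -> list of activated labels"
    },
    "group_summaries": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["group", "size", "cohort_size", "percent_of_cohort", "labels"],
        "properties": {
          "group": {"type": "string"},
          "size": {"type": "integer"},
          "cohort_size": {"type": "integer"},
          "percent_of_cohort": {"type": "integer"},
          "labels": {"type": "object"}
        }
      }
    },
    "triplets": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["labels", "count", "percent"],
        "properties": {
          "labels": {"type": "array", "items": {"type": "string"}},
          "count": {"type": "integer"},
          "percent": {"type": "integer"}
        }
      }
    },
    "menu": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["labels", "count", "new_patients", "cumulative_coverage"],
        "properties": {
          "labels": {"type": "array", "items": {"type": "string"}},
          "count": {"type": "integer"},
          "new_patients": {"type": "integer"},
          "cumulative_coverage": {"type": "integer"}
        }
      }
    }
  }
}
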