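{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mqrc synthetic generator configuration",
  "description": "JSON form of SyntheticConfig accepted by `mqrc simulate --config`. All probability vectors must be nonnegative and sum to 1; rates lie in [0, 1].",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "n_records": {"type": "integer", "minimum": 0, "default": 1000},
    "category_probs": {
      "description": "P(SMQD), P(STF), P(SADR); defaults to the published 52.1/41.6/6.3% mix.",
      "type": "array", "items": {"type": "number", "minimum": 0},
      "minItems": 3, "maxItems": 3, "default": [0.521, 0.416, 0.063]
    },
    "axis_distributions": {
      "description": "axis -> (category value or '*') -> {stratum value: probability}. Omitted axes fall back to defaults derived from the published marginal tables.",
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {
          "type": "object",
          "additionalProperties": {"type": "number", "minimum": 0}
        }
      }
    },
    "duplicate_rate": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.05},
    "test_rate": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.01},
    "missing_county_rate": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.091},
    "out_of_window_rate": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.02},
    "annual_weights": {
      "description": "Relative report volume per study year 2014-2021.",
      "type": "array", "items": {"type": "number", "minimum": 0},
      "minItems": 8, "maxItems": 8,
      "default": [115, 207, 369, 327, 476, 571, 451, 251]
    },
    "seed": {"type": "integer", "default": 0}
  }
}
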