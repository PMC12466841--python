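{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "VetStar tray report",
  "type": "object",
  "required": [
    "schema_version",
    "reagent_source",
    "testing_company",
    "timestamp",
    "tray_layout",
    "results",
    "summary"
  ],
  "properties": {
    "schema_version": {"type": "string"},
    "reagent_source": {"type": "string"},
    "testing_company": {"type": "string"},
    "timestamp": {"type": "string", "description": "ISO-8601 acquisition time"},
    "tray_layout": {"type": "string", "enum": ["strip", "single_card", "triple_card"]},
    "results": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["position_index", "row", "col", "class_label", "confidence", "bbox"],
        "properties": {
          "position_index": {"type": "integer", "minimum": 1},
          "row": {"type": "integer", "minimum": 1},
          "col": {"type": "integer", "minimum": 1},
          "class_label": {"type": "string", "enum": ["negative", "positive"]},
          "confidence": {"type": "number", "minimum": 0, "maximum": 1},
          "bbox": {
            "type": "array",
            "items": {"type": "number"},
            "minItems": 4,
            "maxItems": 4
          }
        }
      }
    },
    "summary": {
      "type": "object",
      "required": ["n_positive", "n_negative"],
      "properties": {
        "n_positive": {"type": "integer", "minimum": 0},
        "n_negative": {"type": "integer", "minimum": 0}
      }
    }
  }
}
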