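{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "imrtqa plan delivery record",
  "description": "Per-segment plan delivery data for a dual-stacked-MLC step-and-shoot IMRT plan; leaf positions in cm at isocenter.",
  "type": "object",
  "required": ["plan_id", "geometry", "segments"],
  "properties": {
    "plan_id": {"type": "string"},
    "geometry": {
      "type": "object",
      "required": ["top_pairs", "bottom_pairs", "leaf_width_iso", "stack_offset", "sad"],
      "properties": {
        "top_pairs": {"type": "integer", "minimum": 1},
        "bottom_pairs": {"type": "integer", "minimum": 1},
        "leaf_width_iso": {"type": "number", "exclusiveMinimum": 0},
        "stack_offset": {"type": "number"},
        "sad": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "segments": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["gantry_deg", "mu", "top_left", "top_right", "bottom_left", "bottom_right"],
        "properties": {
          "gantry_deg": {"type": "number"},
          "mu": {"type": "number", "minimum": 0},
          "top_left": {"type": "array", "items": {"type": "number"}},
          "top_right": {"type": "array", "items": {"type": "number"}},
          "bottom_left": {"type": "array", "items": {"type": "number"}},
          "bottom_right": {"type": "array", "items": {"type": "number"}}
        }
      }
    }
  }
}
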