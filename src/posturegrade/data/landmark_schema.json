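{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "posturegrade landmark file",
  "description": "A list of per-subject, per-plane landmark records. Coordinates are pixels with y increasing UPWARD (image-row conventions must be converted before writing). Sagittal records carry MH, MN, C7, FC, L5, LM; coronal records carry MH, MN, C7, L5.",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["subject_id", "plane", "landmarks"],
    "properties": {
      "subject_id": {"type": "string"},
      "plane": {"enum": ["sagittal", "coronal"]},
      "landmarks": {
        "type": "object",
        "additionalProperties": {
          "type": "array",
          "items": {"type": "number"},
          "minItems": 2,
          "maxItems": 2
        }
      }
    }
  }
}
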