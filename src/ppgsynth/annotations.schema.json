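{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "ppgsynth annotation sidecar",
 "type": "object",
 "required": ["format_version", "fs", "n_samples", "onsets", "beat_labels"],
 "properties": {
  "format_version": {"type": "integer", "const": 1},
  "generator": {"type": "string"},
  "fs": {"type": "number", "exclusiveMinimum": 0},
  "n_samples": {"type": "integer", "minimum": 0},
  "onsets": {"type": "array", "items": {"type": "integer", "minimum": 0}},
  "beat_labels": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["role", "group_type"],
    "properties": {
     "role": {"enum": ["reference", "first", "second"]},
     "group_type": {"enum": [null, "compensation", "reset", "interpolation"]}
    }
   }
  },
  "config": {"type": ["object", "null"]},
  "seed": {"type": ["integer", "null"]}
 }
}
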