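{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "ecogmap functional-map record",
 "type": "object",
 "required": [
  "subject_id", "task", "channel_labels", "bin_times_ms",
  "z_display", "significant", "n_trials"
 ],
 "properties": {
  "format": {"const": "ecogmap-record"},
  "version": {"type": "integer"},
  "subject_id": {"type": "string"},
  "task": {"type": "string"},
  "channel_labels": {"type": "array", "items": {"type": "string"}},
  "bin_times_ms": {"type": "array", "items": {"type": "number"}},
  "z_display": {
   "description": "channels x bins; null marks an untestable entry",
   "type": "array",
   "items": {"type": "array", "items": {"type": ["number", "null"]}}
  },
  "significant": {
   "description": "channels x bins Benjamini-Hochberg mask",
   "type": "array",
   "items": {"type": "array", "items": {"type": "boolean"}}
  },
  "n_trials": {"type": "integer", "minimum": 0},
  "config": {"type": "object"},
  "created": {"type": "string"},
  "truncated": {"type": "boolean"}
 },
 "additionalProperties": true
}
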