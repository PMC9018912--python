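{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "betadose session recording",
  "description": "One hemisphere's streamed-sensing LFP session: channels in microvolts, a per-sample stimulation-amplitude trace in mA, and event annotations (half-open intervals in seconds from recording start).",
  "type": "object",
  "required": [
    "schema_version",
    "subject_id",
    "hemisphere",
    "sampling_rate_hz",
    "channels",
    "stim_trace_mA",
    "events",
    "metadata"
  ],
  "properties": {
    "schema_version": { "const": "1.0" },
    "subject_id": { "type": "string" },
    "hemisphere": { "enum": ["left", "right"] },
    "sampling_rate_hz": { "type": "number", "exclusiveMinimum": 0 },
    "channels": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["label", "samples"],
        "properties": {
          "label": { "type": "string" },
          "samples": { "type": "array", "items": { "type": "number" } }
        }
      }
    },
    "stim_trace_mA": { "type": "array", "items": { "type": "number", "minimum": 0 } },
    "events": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["onset_s", "duration_s", "label"],
        "properties": {
          "onset_s": { "type": "number", "minimum": 0 },
          "duration_s": { "type": "number", "minimum": 0 },
          "label": {
            "type": "string",
            "pattern": "^(rest|tap_block|ramp_down|stim_step:[0-9.]+)$"
          }
        }
      }
    },
    "metadata": { "type": "object" }
  }
}
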