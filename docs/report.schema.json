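{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ctgdiag diagnosis report",
  "type": "object",
  "required": ["trace_label", "criteria", "config", "baselines", "decels", "sustained", "alerts"],
  "properties": {
    "trace_label": {"type": "string"},
    "criteria": {
      "type": "object",
      "required": [
        "tachy_bpm", "brady_bpm", "sustained_min_s", "fall_time_s",
        "uc_lag_s", "depth_bpm", "shoulder_height_bpm", "shoulder_lag_s"
      ],
      "properties": {"patient": {"type": "string"}},
      "additionalProperties": {"type": "number"}
    },
    "config": {"type": "object"},
    "baselines": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["b", "uc_tone", "window"],
        "properties": {
          "b": {"type": "number"},
          "uc_tone": {"type": "number"},
          "window": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2}
        }
      }
    },
    "decels": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["episode", "labels", "ambiguous"],
        "properties": {
          "episode": {"$ref": "#/$defs/decel_episode"},
          "labels": {"type": "array", "items": {"$ref": "#/$defs/label"}},
          "ambiguous": {"type": "boolean"}
        }
      }
    },
    "sustained": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["episode", "label"],
        "properties": {
          "episode": {
            "type": "object",
            "required": ["start", "end", "kind", "extreme_v"],
            "properties": {
              "start": {"type": "number"},
              "end": {"type": "number"},
              "kind": {"enum": ["high", "low"]},
              "extreme_v": {"type": "number"}
            }
          },
          "label": {"$ref": "#/$defs/label"}
        }
      }
    },
    "alerts": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["timestamp", "label", "episode_ref"],
        "properties": {
          "timestamp": {"type": "number"},
          "label": {"type": "string"},
          "episode_ref": {"type": "string"},
          "recipient_hint": {"type": "string"}
        }
      }
    }
  },
  "$defs": {
    "keypoint": {
      "type": "object",
      "required": ["t", "v"],
      "properties": {"t": {"type": "number"}, "v": {"type": "number"}}
    },
    "label": {
      "type": "object",
      "required": ["symptom", "satisfied_rules"],
      "properties": {
        "symptom": {
          "enum": [
            "Tachycardia", "Bradycardia", "EarlyDeceleration",
            "LateDeceleration", "VariableDecelerationA", "VariableDecelerationB"
          ]
        },
        "satisfied_rules": {"type": "array", "items": {"type": "string"}, "minItems": 1}
      }
    },
    "decel_episode": {
      "type": "object",
      "required": ["hrs", "hrp", "hre", "b", "cycle", "shoulder"],
      "properties": {
        "hrs": {"$ref": "#/$defs/keypoint"},
        "hrp": {"$ref": "#/$defs/keypoint"},
        "hre": {"$ref": "#/$defs/keypoint"},
        "b": {"type": "number"},
        "cycle": {
          "oneOf": [
            {"type": "null"},
            {
              "type": "object",
              "required": ["ucs", "ucp", "uce"],
              "properties": {
                "ucs": {"$ref": "#/$defs/keypoint"},
                "ucp": {"$ref": "#/$defs/keypoint"},
                "uce": {"$ref": "#/$defs/keypoint"}
              }
            }
          ]
        },
        "shoulder": {
          "oneOf": [
            {"type": "null"},
            {
              "type": "object",
              "required": ["hsp", "hse"],
              "properties": {
                "hsp": {"$ref": "#/$defs/keypoint"},
                "hse": {"$ref": "#/$defs/keypoint"}
              }
            }
          ]
        }
      }
    }
  }
}
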