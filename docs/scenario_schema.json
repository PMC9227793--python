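{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "empark scenario document",
  "description": "Single-document alternative to the CSV bundle: one array per raw event stream for one patient. Timestamps are ISO 8601, timezone-naive local time.",
  "type": "object",
  "required": ["patient_id", "patient_target"],
  "properties": {
    "patient_id": {"type": "string"},
    "patient_target": {"type": "number", "exclusiveMinimum": 0, "maximum": 100},
    "planned_doses": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["time", "dose"],
        "properties": {
          "time": {"type": "string", "format": "date-time"},
          "dose": {"type": "number", "exclusiveMinimum": 0}
        }
      }
    },
    "taken_doses": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["time", "dose"],
        "properties": {
          "time": {"type": "string", "format": "date-time"},
          "dose": {"type": "number", "exclusiveMinimum": 0},
          "source": {"enum": ["scheduled-delivery", "extra"], "default": "scheduled-delivery"}
        }
      }
    },
    "bed_intervals": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["enter", "leave"],
        "properties": {
          "enter": {"type": "string", "format": "date-time"},
          "leave": {"type": "string", "format": "date-time"}
        }
      }
    },
    "motor_samples": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["time", "bradykinesia", "dyskinesia"],
        "properties": {
          "time": {"type": "string", "format": "date-time"},
          "bradykinesia": {"type": "number", "minimum": 0, "maximum": 100},
          "dyskinesia": {"type": "number", "minimum": 0, "maximum": 100}
        }
      }
    },
    "meals": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["time"],
        "properties": {"time": {"type": "string", "format": "date-time"}}
      }
    },
    "exercise": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["time", "mode", "duration_min"],
        "properties": {
          "time": {"type": "string", "format": "date-time"},
          "mode": {"enum": [1, 2, 3]},
          "duration_min": {"type": "number", "exclusiveMinimum": 0}
        }
      }
    },
    "qol": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["date", "item_levels", "vas"],
        "properties": {
          "date": {"type": "string", "format": "date"},
          "item_levels": {
            "type": "array",
            "minItems": 8,
            "maxItems": 8,
            "items": {"enum": [1, 2, 3]}
          },
          "vas": {"type": "number", "minimum": 0, "maximum": 100}
        }
      }
    }
  }
}
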