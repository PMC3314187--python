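{
  "$defs": {
    "PhaseConfig": {
      "properties": {
        "epochs": {
          "minimum": 1,
          "title": "Epochs",
          "type": "integer"
        },
        "alpha_start": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Alpha Start",
          "type": "number"
        },
        "alpha_end": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Alpha End",
          "type": "number"
        },
        "radius_start": {
          "minimum": 0.0,
          "title": "Radius Start",
          "type": "number"
        },
        "radius_end": {
          "minimum": 0.0,
          "title": "Radius End",
          "type": "number"
        }
      },
      "required": [
        "epochs",
        "alpha_start",
        "alpha_end",
        "radius_start",
        "radius_end"
      ],
      "title": "PhaseConfig",
      "type": "object"
    },
    "QualitySummary": {
      "properties": {
        "quantization_error": {
          "minimum": 0.0,
          "title": "Quantization Error",
          "type": "number"
        },
        "topographic_error": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Topographic Error",
          "type": "number"
        },
        "n_records": {
          "minimum": 1,
          "title": "N Records",
          "type": "integer"
        }
      },
      "required": [
        "quantization_error",
        "topographic_error",
        "n_records"
      ],
      "title": "QualitySummary",
      "type": "object"
    },
    "RunConfig": {
      "description": "Everything needed to reproduce a training run, JSON round-trippable.",
      "properties": {
        "map_rows": {
          "default": 20,
          "minimum": 1,
          "title": "Map Rows",
          "type": "integer"
        },
        "map_cols": {
          "default": 20,
          "minimum": 1,
          "title": "Map Cols",
          "type": "integer"
        },
        "topology": {
          "default": "hexagonal",
          "title": "Topology",
          "type": "string"
        },
        "kernel": {
          "default": "gaussian",
          "title": "Kernel",
          "type": "string"
        },
        "phases": {
          "anyOf": [
            {
              "items": {
                "$ref": "#/$defs/PhaseConfig"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Phases"
        },
        "rough_epochs": {
          "default": 10,
          "minimum": 1,
          "title": "Rough Epochs",
          "type": "integer"
        },
        "fine_epochs": {
          "default": 20,
          "minimum": 1,
          "title": "Fine Epochs",
          "type": "integer"
        },
        "algorithm": {
          "default": "milsom",
          "title": "Algorithm",
          "type": "string"
        },
        "a1": {
          "default": 0.2,
          "minimum": 0.0,
          "title": "A1",
          "type": "number"
        },
        "a2": {
          "default": 0.05,
          "minimum": 0.0,
          "title": "A2",
          "type": "number"
        },
        "windup_cap": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Windup Cap"
        },
        "normalize": {
          "default": true,
          "title": "Normalize",
          "type": "boolean"
        },
        "init": {
          "default": "random_sample",
          "title": "Init",
          "type": "string"
        },
        "seed": {
          "default": 0,
          "title": "Seed",
          "type": "integer"
        }
      },
      "title": "RunConfig",
      "type": "object"
    }
  },
  "description": "Serialized outcome of one training run.",
  "properties": {
    "config": {
      "$ref": "#/$defs/RunConfig"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "algorithm": {
      "title": "Algorithm",
      "type": "string"
    },
    "epochs": {
      "minimum": 1,
      "title": "Epochs",
      "type": "integer"
    },
    "quality": {
      "$ref": "#/$defs/QualitySummary"
    },
    "j_value": {
      "minimum": 0.0,
      "title": "J Value",
      "type": "number"
    },
    "qe_history": {
      "items": {
        "type": "number"
      },
      "title": "Qe History",
      "type": "array"
    },
    "elapsed_seconds": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Elapsed Seconds"
    }
  },
  "required": [
    "config",
    "seed",
    "algorithm",
    "epochs",
    "quality",
    "j_value",
    "qe_history"
  ],
  "title": "RunReport",
  "type": "object"
}
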