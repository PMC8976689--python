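{
  "$defs": {
    "BudgetSummary": {
      "properties": {
        "alpha_margin_s": {
          "title": "Alpha Margin S",
          "type": "number"
        },
        "beam_delay_s": {
          "title": "Beam Delay S",
          "type": "number"
        },
        "frames": {
          "title": "Frames",
          "type": "integer"
        },
        "horizon_s": {
          "title": "Horizon S",
          "type": "number"
        },
        "imaging_s": {
          "title": "Imaging S",
          "type": "number"
        },
        "violations": {
          "title": "Violations",
          "type": "integer"
        }
      },
      "required": [
        "horizon_s",
        "imaging_s",
        "beam_delay_s",
        "alpha_margin_s",
        "frames",
        "violations"
      ],
      "title": "BudgetSummary",
      "type": "object"
    },
    "ErrorSummary": {
      "properties": {
        "max_3d_mm": {
          "title": "Max 3D Mm",
          "type": "number"
        },
        "max_abs_mm": {
          "items": {
            "type": "number"
          },
          "title": "Max Abs Mm",
          "type": "array"
        },
        "per_axis_rmse_mm": {
          "items": {
            "type": "number"
          },
          "title": "Per Axis Rmse Mm",
          "type": "array"
        },
        "phase_rmse_mm": {
          "additionalProperties": {
            "anyOf": [
              {
                "items": {
                  "type": "number"
                },
                "type": "array"
              },
              {
                "type": "null"
              }
            ]
          },
          "title": "Phase Rmse Mm",
          "type": "object"
        }
      },
      "required": [
        "per_axis_rmse_mm",
        "max_abs_mm",
        "max_3d_mm",
        "phase_rmse_mm"
      ],
      "title": "ErrorSummary",
      "type": "object"
    },
    "StageTimes": {
      "properties": {
        "max_s": {
          "title": "Max S",
          "type": "number"
        },
        "mean_s": {
          "title": "Mean S",
          "type": "number"
        }
      },
      "required": [
        "mean_s",
        "max_s"
      ],
      "title": "StageTimes",
      "type": "object"
    }
  },
  "description": "Schema of the JSON summary produced by :func:`report`.",
  "properties": {
    "budget": {
      "$ref": "#/$defs/BudgetSummary"
    },
    "errors": {
      "anyOf": [
        {
          "$ref": "#/$defs/ErrorSummary"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "stages": {
      "additionalProperties": {
        "$ref": "#/$defs/StageTimes"
      },
      "title": "Stages",
      "type": "object"
    }
  },
  "required": [
    "stages",
    "budget"
  ],
  "title": "StreamReport",
  "type": "object"
}
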