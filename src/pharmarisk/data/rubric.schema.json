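{
  "$defs": {
    "CountBand": {
      "description": "One band of a count-based sub-dimension (e.g. instruction count).\n\n``lo`` is inclusive; ``hi`` is inclusive, with ``None`` meaning unbounded.",
      "properties": {
        "hi": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Hi"
        },
        "lo": {
          "minimum": 0,
          "title": "Lo",
          "type": "integer"
        },
        "points": {
          "minimum": 0,
          "title": "Points",
          "type": "integer"
        }
      },
      "required": [
        "lo",
        "points"
      ],
      "title": "CountBand",
      "type": "object"
    },
    "DimensionSpec": {
      "description": "One risk dimension: an ordered list of sub-dimension rules.",
      "properties": {
        "group": {
          "enum": [
            "intrinsic",
            "extrinsic",
            "counterfeit"
          ],
          "title": "Group",
          "type": "string"
        },
        "id": {
          "title": "Id",
          "type": "string"
        },
        "label": {
          "title": "Label",
          "type": "string"
        },
        "max_points": {
          "minimum": 0,
          "title": "Max Points",
          "type": "integer"
        },
        "sub_rules": {
          "items": {
            "$ref": "#/$defs/SubDimensionRule"
          },
          "title": "Sub Rules",
          "type": "array"
        }
      },
      "required": [
        "id",
        "label",
        "group",
        "sub_rules",
        "max_points"
      ],
      "title": "DimensionSpec",
      "type": "object"
    },
    "SeverityBand": {
      "description": "One severity band: scores up to ``max`` (or unbounded) map to ``category``.\n\n``max_inclusive`` controls whether a score equal to ``max`` falls in this\nband or the next one.",
      "properties": {
        "category": {
          "enum": [
            "low",
            "medium",
            "high"
          ],
          "title": "Category",
          "type": "string"
        },
        "max": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Max"
        },
        "max_inclusive": {
          "default": true,
          "title": "Max Inclusive",
          "type": "boolean"
        }
      },
      "required": [
        "category"
      ],
      "title": "SeverityBand",
      "type": "object"
    },
    "SubDimensionRule": {
      "description": "A single scored question inside a dimension.\n\n``answer_kind`` determines how the answer is mapped to points:\n\nbinary\n    answers \"yes\"/\"no\" via ``point_map`` (always {no: 0, yes: 1});\nbanded_count\n    a non-negative integer mapped through contiguous ``bands``;\nenumerated\n    a categorical answer mapped through ``point_map``.",
      "properties": {
        "answer_kind": {
          "enum": [
            "binary",
            "banded_count",
            "enumerated"
          ],
          "title": "Answer Kind",
          "type": "string"
        },
        "bands": {
          "anyOf": [
            {
              "items": {
                "$ref": "#/$defs/CountBand"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Bands"
        },
        "id": {
          "title": "Id",
          "type": "string"
        },
        "label": {
          "title": "Label",
          "type": "string"
        },
        "max_points": {
          "minimum": 0,
          "title": "Max Points",
          "type": "integer"
        },
        "point_map": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Point Map",
          "type": "object"
        }
      },
      "required": [
        "id",
        "label",
        "answer_kind",
        "max_points"
      ],
      "title": "SubDimensionRule",
      "type": "object"
    }
  },
  "description": "Complete scoring configuration.\n\nThe default encodes the eye-drop instrument: four additive dimensions with\nmaxima 4 + 5 + 3 + 2 = 14, a counterfeit override worth 15 points, a\nweighted-score divisor of 10, and severity bands at 0.25 / 0.75.",
  "properties": {
    "dimensions": {
      "items": {
        "$ref": "#/$defs/DimensionSpec"
      },
      "title": "Dimensions",
      "type": "array"
    },
    "local_adr_evidence": {
      "default": true,
      "title": "Local Adr Evidence",
      "type": "boolean"
    },
    "override_score": {
      "default": 15,
      "title": "Override Score",
      "type": "integer"
    },
    "severity_bands": {
      "items": {
        "$ref": "#/$defs/SeverityBand"
      },
      "title": "Severity Bands",
      "type": "array"
    },
    "theoretical_max": {
      "default": 15,
      "title": "Theoretical Max",
      "type": "integer"
    },
    "weighted_divisor": {
      "default": 10.0,
      "exclusiveMinimum": 0,
      "title": "Weighted Divisor",
      "type": "number"
    }
  },
  "required": [
    "dimensions"
  ],
  "title": "RubricConfig",
  "type": "object"
}
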