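{
  "$defs": {
    "CategoryBreakdownModel": {
      "properties": {
        "fine_category_counts": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Fine Category Counts",
          "type": "object"
        },
        "fine_category_pct": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Fine Category Pct",
          "type": "object"
        },
        "gene_category_counts": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Gene Category Counts",
          "type": "object"
        },
        "gene_category_pct": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Gene Category Pct",
          "type": "object"
        },
        "non_coding_count": {
          "title": "Non Coding Count",
          "type": "integer"
        },
        "non_coding_pct": {
          "title": "Non Coding Pct",
          "type": "number"
        },
        "total": {
          "title": "Total",
          "type": "integer"
        }
      },
      "required": [
        "total",
        "gene_category_counts",
        "gene_category_pct",
        "fine_category_counts",
        "fine_category_pct",
        "non_coding_count",
        "non_coding_pct"
      ],
      "title": "CategoryBreakdownModel",
      "type": "object"
    },
    "DistanceModel": {
      "properties": {
        "bootstrap_B": {
          "title": "Bootstrap B",
          "type": "integer"
        },
        "ci_high": {
          "title": "Ci High",
          "type": "number"
        },
        "ci_low": {
          "title": "Ci Low",
          "type": "number"
        },
        "max": {
          "title": "Max",
          "type": "number"
        },
        "min": {
          "title": "Min",
          "type": "number"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "percentile_95": {
          "title": "Percentile 95",
          "type": "number"
        },
        "reliable": {
          "title": "Reliable",
          "type": "boolean"
        },
        "seed": {
          "title": "Seed",
          "type": "integer"
        }
      },
      "required": [
        "n",
        "min",
        "max",
        "percentile_95",
        "ci_low",
        "ci_high",
        "reliable",
        "bootstrap_B",
        "seed"
      ],
      "title": "DistanceModel",
      "type": "object"
    },
    "RegionActivityModel": {
      "properties": {
        "activating": {
          "title": "Activating",
          "type": "number"
        },
        "both": {
          "title": "Both",
          "type": "number"
        },
        "n_studies": {
          "title": "N Studies",
          "type": "integer"
        },
        "repressive": {
          "title": "Repressive",
          "type": "number"
        }
      },
      "required": [
        "n_studies",
        "activating",
        "repressive",
        "both"
      ],
      "title": "RegionActivityModel",
      "type": "object"
    },
    "TechniqueThroughputModel": {
      "properties": {
        "max_per_study": {
          "title": "Max Per Study",
          "type": "integer"
        },
        "mean_per_study": {
          "title": "Mean Per Study",
          "type": "number"
        },
        "n_studies": {
          "title": "N Studies",
          "type": "integer"
        },
        "total": {
          "title": "Total",
          "type": "integer"
        }
      },
      "required": [
        "n_studies",
        "total",
        "max_per_study",
        "mean_per_study"
      ],
      "title": "TechniqueThroughputModel",
      "type": "object"
    }
  },
  "description": "Schema of the machine-readable report (also shipped as JSON Schema).",
  "properties": {
    "activity": {
      "additionalProperties": {
        "anyOf": [
          {
            "$ref": "#/$defs/RegionActivityModel"
          },
          {
            "type": "null"
          }
        ]
      },
      "default": {},
      "title": "Activity",
      "type": "object"
    },
    "categories": {
      "anyOf": [
        {
          "$ref": "#/$defs/CategoryBreakdownModel"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "distances": {
      "anyOf": [
        {
          "$ref": "#/$defs/DistanceModel"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "inputs": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Inputs",
      "type": "object"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "throughput": {
      "additionalProperties": {
        "anyOf": [
          {
            "$ref": "#/$defs/TechniqueThroughputModel"
          },
          {
            "type": "null"
          }
        ]
      },
      "default": {},
      "title": "Throughput",
      "type": "object"
    },
    "version": {
      "title": "Version",
      "type": "string"
    }
  },
  "required": [
    "version",
    "seed",
    "inputs"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
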