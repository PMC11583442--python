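{
  "$defs": {
    "ExplanationConfig": {
      "additionalProperties": false,
      "properties": {
        "on": {
          "default": "test",
          "enum": [
            "train",
            "test",
            "both"
          ],
          "title": "On",
          "type": "string"
        },
        "top_n": {
          "default": 15,
          "minimum": 1,
          "title": "Top N",
          "type": "integer"
        }
      },
      "title": "ExplanationConfig",
      "type": "object"
    },
    "FeatureSelectionConfig": {
      "additionalProperties": false,
      "properties": {
        "auto_max": {
          "default": 100,
          "minimum": 2,
          "title": "Auto Max",
          "type": "integer"
        },
        "auto_min": {
          "default": 10,
          "minimum": 1,
          "title": "Auto Min",
          "type": "integer"
        },
        "k": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "const": "auto",
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "K"
        },
        "variance_threshold": {
          "default": 0.0,
          "minimum": 0.0,
          "title": "Variance Threshold",
          "type": "number"
        }
      },
      "title": "FeatureSelectionConfig",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "balancing": {
      "default": "none",
      "enum": [
        "none",
        "oversample",
        "undersample"
      ],
      "title": "Balancing",
      "type": "string"
    },
    "collapse_tax": {
      "anyOf": [
        {
          "enum": [
            "k",
            "p",
            "c",
            "o",
            "f",
            "g",
            "s"
          ],
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Collapse Tax"
    },
    "data_path": {
      "title": "Data Path",
      "type": "string"
    },
    "data_type": {
      "default": "none",
      "enum": [
        "gene_expression",
        "microbiome",
        "metabolomic",
        "tabular",
        "none"
      ],
      "title": "Data Type",
      "type": "string"
    },
    "explanations": {
      "$ref": "#/$defs/ExplanationConfig"
    },
    "expression_type": {
      "anyOf": [
        {
          "enum": [
            "FPKM",
            "RPKM",
            "TMM",
            "TPM",
            "Log2FC",
            "COUNTS",
            "OTHER"
          ],
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Expression Type"
    },
    "feature_selection": {
      "anyOf": [
        {
          "$ref": "#/$defs/FeatureSelectionConfig"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "filter_abundance": {
      "default": 10.0,
      "minimum": 0.0,
      "title": "Filter Abundance",
      "type": "number"
    },
    "filter_feature_min": {
      "anyOf": [
        {
          "maxItems": 2,
          "minItems": 2,
          "prefixItems": [
            {
              "type": "number"
            },
            {
              "type": "integer"
            }
          ],
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Filter Feature Min"
    },
    "filter_microbiome_samples": {
      "anyOf": [
        {
          "items": {
            "additionalProperties": {
              "type": "string"
            },
            "type": "object"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Filter Microbiome Samples"
    },
    "filter_prevalence": {
      "default": 0.01,
      "maximum": 1.0,
      "minimum": 0.0,
      "title": "Filter Prevalence",
      "type": "number"
    },
    "filter_sample_sd": {
      "anyOf": [
        {
          "minimum": 0.0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Filter Sample Sd"
    },
    "hyper_tuning": {
      "default": "random",
      "enum": [
        "random",
        "grid",
        "none"
      ],
      "title": "Hyper Tuning",
      "type": "string"
    },
    "merge_classes": {
      "anyOf": [
        {
          "additionalProperties": {
            "items": {
              "type": "string"
            },
            "type": "array"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Merge Classes"
    },
    "metadata_path": {
      "title": "Metadata Path",
      "type": "string"
    },
    "min_reads": {
      "default": 1000,
      "minimum": 0,
      "title": "Min Reads",
      "type": "integer"
    },
    "models": {
      "items": {
        "type": "string"
      },
      "title": "Models",
      "type": "array"
    },
    "norm_reads": {
      "default": 1000,
      "minimum": 0,
      "title": "Norm Reads",
      "type": "integer"
    },
    "plots": {
      "items": {
        "type": "string"
      },
      "title": "Plots",
      "type": "array"
    },
    "problem_type": {
      "enum": [
        "classification",
        "regression"
      ],
      "title": "Problem Type",
      "type": "string"
    },
    "remove_classes": {
      "anyOf": [
        {
          "items": {
            "type": "string"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Remove Classes"
    },
    "scoring": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Scoring"
    },
    "seed": {
      "default": 42,
      "title": "Seed",
      "type": "integer"
    },
    "target_column": {
      "title": "Target Column",
      "type": "string"
    },
    "test_size": {
      "default": 0.2,
      "exclusiveMaximum": 1.0,
      "exclusiveMinimum": 0.0,
      "title": "Test Size",
      "type": "number"
    }
  },
  "required": [
    "data_path",
    "metadata_path",
    "target_column",
    "problem_type"
  ],
  "title": "RunConfig",
  "type": "object"
}
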