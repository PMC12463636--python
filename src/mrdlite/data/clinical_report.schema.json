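{
  "$defs": {
    "MrdBlock": {
      "properties": {
        "blast_events": {
          "title": "Blast Events",
          "type": "integer"
        },
        "category": {
          "title": "Category",
          "type": "string"
        },
        "correction_factor": {
          "title": "Correction Factor",
          "type": "number"
        },
        "denominator_raw": {
          "title": "Denominator Raw",
          "type": "integer"
        },
        "limited_sensitivity": {
          "title": "Limited Sensitivity",
          "type": "boolean"
        },
        "lod_met": {
          "title": "Lod Met",
          "type": "boolean"
        },
        "mrd_corrected_pct": {
          "title": "Mrd Corrected Pct",
          "type": "number"
        },
        "mrd_raw_pct": {
          "title": "Mrd Raw Pct",
          "type": "number"
        },
        "phenotype_used": {
          "items": {
            "type": "string"
          },
          "title": "Phenotype Used",
          "type": "array"
        },
        "suitable": {
          "title": "Suitable",
          "type": "boolean"
        }
      },
      "required": [
        "suitable",
        "blast_events",
        "denominator_raw",
        "correction_factor",
        "mrd_raw_pct",
        "mrd_corrected_pct",
        "lod_met",
        "category",
        "limited_sensitivity",
        "phenotype_used"
      ],
      "title": "MrdBlock",
      "type": "object"
    },
    "ProvenanceBlock": {
      "properties": {
        "config_hash": {
          "title": "Config Hash",
          "type": "string"
        },
        "gate_counts": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Gate Counts",
          "type": "object"
        },
        "software_version": {
          "title": "Software Version",
          "type": "string"
        }
      },
      "required": [
        "config_hash",
        "software_version",
        "gate_counts"
      ],
      "title": "ProvenanceBlock",
      "type": "object"
    },
    "RiskBlock": {
      "properties": {
        "group": {
          "title": "Group",
          "type": "string"
        },
        "trace": {
          "items": {
            "items": {},
            "type": "array"
          },
          "title": "Trace",
          "type": "array"
        },
        "workflow": {
          "title": "Workflow",
          "type": "string"
        }
      },
      "required": [
        "group",
        "workflow",
        "trace"
      ],
      "title": "RiskBlock",
      "type": "object"
    }
  },
  "properties": {
    "disclaimers": {
      "items": {
        "type": "string"
      },
      "title": "Disclaimers",
      "type": "array"
    },
    "hemodilution_factor": {
      "title": "Hemodilution Factor",
      "type": "number"
    },
    "mrd": {
      "$ref": "#/$defs/MrdBlock"
    },
    "n_events": {
      "title": "N Events",
      "type": "integer"
    },
    "preparation": {
      "title": "Preparation",
      "type": "string"
    },
    "provenance": {
      "$ref": "#/$defs/ProvenanceBlock"
    },
    "risk_original": {
      "$ref": "#/$defs/RiskBlock"
    },
    "risk_updated": {
      "$ref": "#/$defs/RiskBlock"
    },
    "sample_id": {
      "title": "Sample Id",
      "type": "string"
    },
    "true_blast_fraction_of_nucleated": {
      "title": "True Blast Fraction Of Nucleated",
      "type": "number"
    }
  },
  "required": [
    "sample_id",
    "preparation",
    "n_events",
    "hemodilution_factor",
    "true_blast_fraction_of_nucleated",
    "mrd",
    "risk_original",
    "risk_updated",
    "disclaimers",
    "provenance"
  ],
  "title": "ClinicalReport",
  "type": "object"
}
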