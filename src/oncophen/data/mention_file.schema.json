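{
  "$defs": {
    "CodedValue": {
      "properties": {
        "code": {
          "title": "Code",
          "type": "string"
        },
        "kind": {
          "const": "coded",
          "default": "coded",
          "title": "Kind",
          "type": "string"
        },
        "label": {
          "default": "",
          "title": "Label",
          "type": "string"
        }
      },
      "required": [
        "code"
      ],
      "title": "CodedValue",
      "type": "object"
    },
    "ConceptRef": {
      "description": "A coded concept: vocabulary code, preferred term, semantic class.",
      "properties": {
        "code": {
          "title": "Code",
          "type": "string"
        },
        "label": {
          "default": "",
          "title": "Label",
          "type": "string"
        },
        "semantic_class": {
          "$ref": "#/$defs/SemanticClass"
        }
      },
      "required": [
        "code",
        "semantic_class"
      ],
      "title": "ConceptRef",
      "type": "object"
    },
    "DocTimeRel": {
      "description": "Temporal relation of an event to its document's creation time.",
      "enum": [
        "BEFORE",
        "OVERLAP",
        "AFTER",
        "BEFORE_OVERLAP"
      ],
      "title": "DocTimeRel",
      "type": "string"
    },
    "DocType": {
      "enum": [
        "radiology",
        "pathology",
        "progress_note",
        "discharge_summary",
        "other"
      ],
      "title": "DocType",
      "type": "string"
    },
    "Mention": {
      "description": "A span-anchored coded annotation from one clinical document.\n\nSpans are 0-based half-open character offsets into the source text.",
      "properties": {
        "concept": {
          "$ref": "#/$defs/ConceptRef"
        },
        "doc_time_rel": {
          "$ref": "#/$defs/DocTimeRel",
          "default": "OVERLAP"
        },
        "document_id": {
          "title": "Document Id",
          "type": "string"
        },
        "id": {
          "title": "Id",
          "type": "string"
        },
        "polarity": {
          "$ref": "#/$defs/Polarity",
          "default": "affirmed"
        },
        "span": {
          "maxItems": 2,
          "minItems": 2,
          "prefixItems": [
            {
              "type": "integer"
            },
            {
              "type": "integer"
            }
          ],
          "title": "Span",
          "type": "array"
        },
        "text": {
          "default": "",
          "title": "Text",
          "type": "string"
        },
        "uncertainty": {
          "$ref": "#/$defs/Uncertainty",
          "default": "certain"
        },
        "value": {
          "anyOf": [
            {
              "discriminator": {
                "mapping": {
                  "coded": "#/$defs/CodedValue",
                  "quantity": "#/$defs/QuantityValue",
                  "text": "#/$defs/TextValue"
                },
                "propertyName": "kind"
              },
              "oneOf": [
                {
                  "$ref": "#/$defs/CodedValue"
                },
                {
                  "$ref": "#/$defs/QuantityValue"
                },
                {
                  "$ref": "#/$defs/TextValue"
                }
              ]
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Value"
        }
      },
      "required": [
        "id",
        "document_id",
        "span",
        "concept"
      ],
      "title": "Mention",
      "type": "object"
    },
    "Polarity": {
      "enum": [
        "affirmed",
        "negated"
      ],
      "title": "Polarity",
      "type": "string"
    },
    "QuantityValue": {
      "properties": {
        "kind": {
          "const": "quantity",
          "default": "quantity",
          "title": "Kind",
          "type": "string"
        },
        "unit": {
          "default": "",
          "title": "Unit",
          "type": "string"
        },
        "value": {
          "title": "Value",
          "type": "number"
        }
      },
      "required": [
        "value"
      ],
      "title": "QuantityValue",
      "type": "object"
    },
    "SemanticClass": {
      "enum": [
        "Condition",
        "Procedure",
        "Medication",
        "Observation",
        "AnatomicalSite"
      ],
      "title": "SemanticClass",
      "type": "string"
    },
    "TextValue": {
      "properties": {
        "kind": {
          "const": "text",
          "default": "text",
          "title": "Kind",
          "type": "string"
        },
        "text": {
          "title": "Text",
          "type": "string"
        }
      },
      "required": [
        "text"
      ],
      "title": "TextValue",
      "type": "object"
    },
    "Uncertainty": {
      "enum": [
        "certain",
        "uncertain"
      ],
      "title": "Uncertainty",
      "type": "string"
    },
    "_DocumentMeta": {
      "properties": {
        "date": {
          "format": "date",
          "title": "Date",
          "type": "string"
        },
        "doc_type": {
          "$ref": "#/$defs/DocType",
          "default": "other"
        },
        "id": {
          "title": "Id",
          "type": "string"
        },
        "patient_id": {
          "title": "Patient Id",
          "type": "string"
        }
      },
      "required": [
        "id",
        "patient_id",
        "date"
      ],
      "title": "_DocumentMeta",
      "type": "object"
    }
  },
  "description": "The mention-file interchange format (one clinical document).",
  "properties": {
    "document": {
      "$ref": "#/$defs/_DocumentMeta"
    },
    "format": {
      "default": "oncophen-mentions-1",
      "title": "Format",
      "type": "string"
    },
    "mentions": {
      "items": {
        "$ref": "#/$defs/Mention"
      },
      "title": "Mentions",
      "type": "array"
    }
  },
  "required": [
    "document"
  ],
  "title": "MentionFile",
  "type": "object"
}
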