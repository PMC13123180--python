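{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Identifier codebook",
  "description": "Structural schema for the YAML codebook: two entity sections whose fields are either controlled vocabularies (entries with code/stub_code and optional ontologyClass annotations) or anchored-pattern definitions, plus optional byte-exact condition stub overrides.",
  "type": "object",
  "required": ["biosample", "subject"],
  "properties": {
    "version": {"type": "string"},
    "biosample": {
      "type": "object",
      "required": ["project", "species", "subject_id", "tissue", "sample_type", "assay", "condition", "timepoint", "duration", "batch", "replicate"],
      "additionalProperties": {
        "type": "object",
        "properties": {
          "pattern": {"type": "string", "minLength": 1},
          "human_width": {"type": "integer", "minimum": 1},
          "stub_width": {"type": "integer", "minimum": 1}
        },
        "additionalProperties": {
          "type": "object",
          "required": ["stub_code"],
          "properties": {
            "code": {"type": "string", "minLength": 1},
            "stub_code": {"type": "string", "minLength": 1},
            "id": {"type": "string", "pattern": "^[A-Za-z_][A-Za-z0-9_.-]*:\\S+$"},
            "label": {"type": "string", "minLength": 1},
            "tax_code": {"type": "string", "pattern": "^[A-Z]{3}$"}
          },
          "additionalProperties": false
        }
      }
    },
    "subject": {
      "type": "object",
      "required": ["study", "subject_id", "type", "condition", "sex", "age_group"],
      "additionalProperties": {
        "type": "object",
        "properties": {
          "pattern": {"type": "string", "minLength": 1},
          "human_width": {"type": "integer", "minimum": 1},
          "stub_width": {"type": "integer", "minimum": 1}
        },
        "additionalProperties": {
          "type": "object",
          "required": ["stub_code"],
          "properties": {
            "code": {"type": "string", "minLength": 1},
            "stub_code": {"type": "string", "minLength": 1},
            "id": {"type": "string", "pattern": "^[A-Za-z_][A-Za-z0-9_.-]*:\\S+$"},
            "label": {"type": "string", "minLength": 1},
            "tax_code": {"type": "string", "pattern": "^[A-Z]{3}$"}
          },
          "additionalProperties": false
        }
      }
    },
    "condition_stub_overrides": {
      "type": "object",
      "patternProperties": {
        "^[A-Z][0-9]{2}(\\.[0-9]{1,2})?$": {
          "type": "string",
          "pattern": "^[0-9A-Za-z]{5}$"
        }
      },
      "additionalProperties": false
    }
  }
}
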