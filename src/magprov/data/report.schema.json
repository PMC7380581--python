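{
  "description": "Schema of report.json (shipped alongside as report.schema.json).",
  "properties": {
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "bins": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Bins",
      "type": "array"
    },
    "presence_matrix": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Presence Matrix"
    },
    "hgt_reports": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Hgt Reports",
      "type": "array"
    },
    "congruence": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Congruence",
      "type": "array"
    },
    "aai": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Aai",
      "type": "array"
    },
    "notices": {
      "items": {
        "type": "string"
      },
      "title": "Notices",
      "type": "array"
    }
  },
  "required": [
    "config",
    "bins"
  ],
  "title": "ReportBundle",
  "type": "object"
}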