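{
  "description": "Metadata describing a grouping methodology.",
  "properties": {
    "description": {
      "default": "",
      "title": "Description",
      "type": "string"
    },
    "granularity": {
      "enum": [
        "entry",
        "entity"
      ],
      "title": "Granularity",
      "type": "string"
    },
    "method": {
      "enum": [
        "deposition",
        "reference_accession",
        "sequence_identity"
      ],
      "title": "Method",
      "type": "string"
    },
    "software_name": {
      "default": "structgroups",
      "title": "Software Name",
      "type": "string"
    },
    "version": {
      "default": "0.1.0",
      "title": "Version",
      "type": "string"
    }
  },
  "required": [
    "method",
    "granularity"
  ],
  "title": "GroupProvenanceRecord",
  "type": "object"
}
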