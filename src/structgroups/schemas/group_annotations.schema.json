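{
  "$defs": {
    "TrackModel": {
      "properties": {
        "kind": {
          "title": "Kind",
          "type": "string"
        },
        "track_id": {
          "title": "Track Id",
          "type": "string"
        },
        "values": {
          "items": {},
          "title": "Values",
          "type": "array"
        }
      },
      "required": [
        "track_id",
        "kind",
        "values"
      ],
      "title": "TrackModel",
      "type": "object"
    }
  },
  "description": "Positional annotations, either aggregated over the MSA (histogram\nmode) or as per-member feature lists with their column mappings.",
  "properties": {
    "group_id": {
      "title": "Group Id",
      "type": "string"
    },
    "mode": {
      "enum": [
        "per_member",
        "histogram"
      ],
      "title": "Mode",
      "type": "string"
    },
    "per_member": {
      "additionalProperties": {
        "items": {
          "additionalProperties": true,
          "type": "object"
        },
        "type": "array"
      },
      "title": "Per Member",
      "type": "object"
    },
    "schema_version": {
      "default": "1.0",
      "title": "Schema Version",
      "type": "string"
    },
    "tracks": {
      "items": {
        "$ref": "#/$defs/TrackModel"
      },
      "title": "Tracks",
      "type": "array"
    }
  },
  "required": [
    "group_id",
    "mode"
  ],
  "title": "GroupAnnotationsDocument",
  "type": "object"
}
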