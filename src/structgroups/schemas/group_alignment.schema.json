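{
  "$defs": {
    "AlignedRegionModel": {
      "properties": {
        "column_begin": {
          "minimum": 1,
          "title": "Column Begin",
          "type": "integer"
        },
        "column_end": {
          "minimum": 1,
          "title": "Column End",
          "type": "integer"
        },
        "member_begin": {
          "minimum": 1,
          "title": "Member Begin",
          "type": "integer"
        },
        "member_end": {
          "minimum": 1,
          "title": "Member End",
          "type": "integer"
        }
      },
      "required": [
        "member_begin",
        "member_end",
        "column_begin",
        "column_end"
      ],
      "title": "AlignedRegionModel",
      "type": "object"
    },
    "MemberAlignmentModel": {
      "properties": {
        "aligned_regions": {
          "items": {
            "$ref": "#/$defs/AlignedRegionModel"
          },
          "title": "Aligned Regions",
          "type": "array"
        },
        "member_uid": {
          "title": "Member Uid",
          "type": "string"
        }
      },
      "required": [
        "member_uid",
        "aligned_regions"
      ],
      "title": "MemberAlignmentModel",
      "type": "object"
    },
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
  "description": "The group MSA as aligned regions per member, with optional summary\ntracks recomputed over the emitted member set.",
  "properties": {
    "consensus": {
      "anyOf": [
        {
          "$ref": "#/$defs/TrackModel"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "group_id": {
      "title": "Group Id",
      "type": "string"
    },
    "members": {
      "items": {
        "$ref": "#/$defs/MemberAlignmentModel"
      },
      "title": "Members",
      "type": "array"
    },
    "n_columns": {
      "title": "N Columns",
      "type": "integer"
    },
    "reference": {
      "title": "Reference",
      "type": "string"
    },
    "schema_version": {
      "default": "1.0",
      "title": "Schema Version",
      "type": "string"
    },
    "variation": {
      "anyOf": [
        {
          "$ref": "#/$defs/TrackModel"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "group_id",
    "reference",
    "n_columns",
    "members"
  ],
  "title": "GroupAlignmentDocument",
  "type": "object"
}
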