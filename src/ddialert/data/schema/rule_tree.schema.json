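{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "DDI decision-tree document",
 "type": "object",
 "required": [
  "ddi_id",
  "object_set",
  "precipitant_set",
  "factors",
  "root",
  "nodes"
 ],
 "properties": {
  "ddi_id": {
   "type": "string"
  },
  "name": {
   "type": "string"
  },
  "object_set": {
   "type": "string"
  },
  "precipitant_set": {
   "type": "string"
  },
  "monotone_severity": {
   "type": "boolean",
   "default": false
  },
  "factors": {
   "type": "array",
   "items": {
    "type": "object",
    "required": [
     "name",
     "type",
     "extractor"
    ],
    "properties": {
     "name": {
      "type": "string"
     },
     "type": {
      "enum": [
       "number",
       "boolean",
       "enum",
       "count"
      ]
     },
     "extractor": {
      "type": "string"
     },
     "params": {
      "type": "object"
     }
    }
   }
  },
  "root": {
   "type": "string"
  },
  "nodes": {
   "type": "object",
   "additionalProperties": {
    "oneOf": [
     {
      "type": "object",
      "required": [
       "kind",
       "leaf_id",
       "color"
      ],
      "properties": {
       "kind": {
        "const": "LEAF"
       },
       "leaf_id": {
        "type": "string"
       },
       "color": {
        "enum": [
         "RED",
         "YELLOW",
         "GREEN"
        ]
       }
      }
     },
     {
      "type": "object",
      "required": [
       "kind",
       "factor",
       "comparator",
       "true_branch",
       "false_branch"
      ],
      "properties": {
       "kind": {
        "const": "PREDICATE"
       },
       "factor": {
        "type": "string"
       },
       "comparator": {
        "enum": [
         "LT",
         "LE",
         "GT",
         "GE",
         "EQ",
         "IN_SET",
         "PRESENT",
         "ABSENT"
        ]
       },
       "threshold": {},
       "missing_branch": {
        "enum": [
         "TRUE_BRANCH",
         "FALSE_BRANCH"
        ]
       },
       "true_branch": {
        "type": "string"
       },
       "false_branch": {
        "type": "string"
       }
      }
     }
    ]
   }
  }
 }
}
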