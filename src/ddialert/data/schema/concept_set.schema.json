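{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "Concept set definition",
 "type": "object",
 "required": [
  "set_id",
  "name",
  "vocabulary",
  "seed_concept_ids"
 ],
 "properties": {
  "set_id": {
   "type": "string"
  },
  "name": {
   "type": "string"
  },
  "vocabulary": {
   "enum": [
    "RXNORM",
    "LOINC",
    "SNOMED"
   ]
  },
  "seed_concept_ids": {
   "type": "array",
   "items": {
    "type": "integer"
   },
   "minItems": 1
  },
  "include_descendants": {
   "type": "boolean",
   "default": false
  },
  "excluded_concept_ids": {
   "type": "array",
   "items": {
    "type": "integer"
   }
  }
 }
}
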