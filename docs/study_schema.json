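{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "dmsprof study (schema_version 1)",
 "type": "object",
 "required": ["schema_version", "references", "sections", "samples"],
 "properties": {
  "schema_version": {"const": "1"},
  "references": {
   "type": "object",
   "additionalProperties": {"type": "string", "pattern": "^[ACGTN]*$"}
  },
  "sections": {
   "type": "object",
   "additionalProperties": {
    "type": "array",
    "items": {
     "type": "object",
     "required": ["name", "role", "start", "end"],
     "properties": {
      "name": {"type": "string"},
      "role": {"enum": ["primer5", "barcode", "flank5", "roi", "flank3", "primer3", "full"]},
      "start": {"type": "integer", "minimum": 1},
      "end": {"type": "integer", "minimum": 1}
     }
    }
   }
  },
  "samples": {
   "type": "object",
   "additionalProperties": {
    "type": "object",
    "properties": {
     "variables": {
      "type": "object",
      "additionalProperties": {
       "type": "object",
       "properties": {"value": {}, "unit": {"type": ["string", "null"]}}
      }
     },
     "aligned_reads": {
      "type": "object",
      "additionalProperties": {"type": "integer", "minimum": 0}
     },
     "read_hists": {
      "type": "object",
      "additionalProperties": {
       "type": "object",
       "required": ["bin_edges", "counts", "total_reads"],
       "properties": {
        "bin_edges": {"type": "array", "items": {"type": "integer"}},
        "counts": {"type": "array", "items": {"type": "integer", "minimum": 0}},
        "total_reads": {"type": "integer", "minimum": 0}
       }
      }
     },
     "profiles": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["reference", "section", "positions", "base", "coverage", "mutated"],
       "properties": {
        "reference": {"type": "string"},
        "section": {"type": "string"},
        "positions": {"type": "array", "items": {"type": "integer", "minimum": 1}},
        "base": {"type": "string", "pattern": "^[ACGTN]*$"},
        "coverage": {"type": "array", "items": {"type": "integer", "minimum": 0}},
        "mutated": {"type": "array", "items": {"type": "integer", "minimum": 0}},
        "sub_counts": {
         "type": ["object", "null"],
         "properties": {
          "A": {"type": "array", "items": {"type": "integer", "minimum": 0}},
          "C": {"type": "array", "items": {"type": "integer", "minimum": 0}},
          "G": {"type": "array", "items": {"type": "integer", "minimum": 0}},
          "T": {"type": "array", "items": {"type": "integer", "minimum": 0}}
         }
        },
        "fraction": {
         "type": ["array", "null"],
         "items": {"type": ["number", "null"], "minimum": 0, "maximum": 1}
        }
       }
      }
     }
    }
   }
  },
  "provenance": {"type": "object"}
 }
}
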