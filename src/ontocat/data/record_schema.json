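{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/ontocat/record.schema.json",
  "title": "OntologyRecord",
  "description": "Curated metadata for one ontology across the six catalog sections.",
  "type": "object",
  "required": ["general", "references", "modeling", "classification", "characteristics", "comments"],
  "additionalProperties": false,
  "$defs": {
    "relatedness": {
      "enum": ["missing", "related:broader", "related:narrower", "contained"]
    },
    "nullableString": {"type": ["string", "null"]},
    "stringList": {"type": "array", "items": {"type": "string"}},
    "nullableCount": {
      "oneOf": [{"type": "integer", "minimum": 0}, {"type": "null"}]
    }
  },
  "properties": {
    "general": {
      "type": "object",
      "required": ["name", "acronym"],
      "properties": {
        "name": {"$ref": "#/$defs/nullableString"},
        "alternative_names": {"$ref": "#/$defs/stringList"},
        "acronym": {"type": "string", "minLength": 1},
        "creators": {"$ref": "#/$defs/stringList"},
        "issuing_organization": {"$ref": "#/$defs/nullableString"},
        "organizational_structure": {"$ref": "#/$defs/nullableString"}
      }
    },
    "references": {
      "type": "object",
      "properties": {
        "organization_url": {"$ref": "#/$defs/nullableString"},
        "persistent_uri": {"$ref": "#/$defs/nullableString"},
        "documentation_url": {"$ref": "#/$defs/nullableString"},
        "version_directory_url": {"$ref": "#/$defs/nullableString"},
        "additional_links": {"$ref": "#/$defs/stringList"}
      }
    },
    "modeling": {
      "type": "object",
      "properties": {
        "formats": {"$ref": "#/$defs/stringList"},
        "inference_degree": {"$ref": "#/$defs/nullableString"},
        "license": {"$ref": "#/$defs/nullableString"},
        "working_reasoners": {"$ref": "#/$defs/stringList"},
        "shortest_reasoning_time": {"$ref": "#/$defs/nullableString"},
        "top_level_alignment": {"$ref": "#/$defs/nullableString"},
        "imports": {"$ref": "#/$defs/stringList"},
        "prefixes": {"$ref": "#/$defs/stringList"},
        "class_annotation_types": {"$ref": "#/$defs/stringList"}
      }
    },
    "classification": {
      "type": "object",
      "required": ["relatedness", "top_level_ontology"],
      "properties": {
        "relatedness": {
          "type": "object",
          "minProperties": 14,
          "maxProperties": 14,
          "additionalProperties": {"$ref": "#/$defs/relatedness"}
        },
        "top_level_ontology": {"type": "boolean"}
      }
    },
    "characteristics": {
      "type": "object",
      "properties": {
        "axiom_count": {"$ref": "#/$defs/nullableCount"},
        "logical_axiom_count": {"$ref": "#/$defs/nullableCount"},
        "declaration_count": {"$ref": "#/$defs/nullableCount"},
        "class_count": {"$ref": "#/$defs/nullableCount"},
        "object_property_count": {"$ref": "#/$defs/nullableCount"},
        "data_property_count": {"$ref": "#/$defs/nullableCount"},
        "individual_count": {"$ref": "#/$defs/nullableCount"},
        "annotation_property_count": {"$ref": "#/$defs/nullableCount"}
      }
    },
    "comments": {"$ref": "#/$defs/nullableString"}
  }
}
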