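{
  "general": {
    "name": null,
    "alternative_names": [],
    "acronym": null,
    "creators": [],
    "issuing_organization": null,
    "organizational_structure": null
  },
  "references": {
    "organization_url": null,
    "persistent_uri": null,
    "documentation_url": null,
    "version_directory_url": null,
    "additional_links": []
  },
  "modeling": {
    "formats": [],
    "inference_degree": null,
    "license": null,
    "working_reasoners": [],
    "shortest_reasoning_time": null,
    "top_level_alignment": null,
    "imports": [],
    "prefixes": [],
    "class_annotation_types": []
  },
  "classification": {
    "relatedness": {
      "Biocatalysis": "missing",
      "Heterogeneous catalysis": "missing",
      "Homogeneous catalysis": "missing",
      "Photocatalysis": "missing",
      "Electrocatalysis": "missing",
      "Chemical substance modelling": "missing",
      "Material modelling": "missing",
      "Process modelling": "missing",
      "Synthesis data": "missing",
      "Operando data": "missing",
      "Performance data": "missing",
      "Characterisation data": "missing",
      "Heat, transport and kinetic data": "missing",
      "Process design, energy and cost data": "missing"
    },
    "top_level_ontology": false
  },
  "characteristics": {
    "axiom_count": null,
    "logical_axiom_count": null,
    "declaration_count": null,
    "class_count": null,
    "object_property_count": null,
    "data_property_count": null,
    "individual_count": null,
    "annotation_property_count": null
  },
  "comments": null
}
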