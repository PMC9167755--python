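{
  "$defs": {
    "BundleEdge": {
      "additionalProperties": false,
      "properties": {
        "bidirectional": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Bidirectional"
        },
        "contact_level": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Contact Level"
        },
        "source": {
          "title": "Source",
          "type": "string"
        },
        "target": {
          "title": "Target",
          "type": "string"
        }
      },
      "required": [
        "source",
        "target"
      ],
      "title": "BundleEdge",
      "type": "object"
    },
    "BundleLayer": {
      "additionalProperties": false,
      "properties": {
        "contact_threshold": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Contact Threshold"
        },
        "directed": {
          "title": "Directed",
          "type": "boolean"
        },
        "edges": {
          "items": {
            "$ref": "#/$defs/BundleEdge"
          },
          "title": "Edges",
          "type": "array"
        },
        "key": {
          "title": "Key",
          "type": "string"
        },
        "network": {
          "$ref": "#/$defs/BundleNetworkStats"
        },
        "nodes": {
          "items": {
            "$ref": "#/$defs/BundleNode"
          },
          "title": "Nodes",
          "type": "array"
        },
        "relationship": {
          "title": "Relationship",
          "type": "string"
        }
      },
      "required": [
        "key",
        "relationship",
        "directed",
        "nodes",
        "edges",
        "network"
      ],
      "title": "BundleLayer",
      "type": "object"
    },
    "BundleNetworkStats": {
      "additionalProperties": false,
      "properties": {
        "average_degree": {
          "title": "Average Degree",
          "type": "number"
        },
        "betweenness_centralization": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Betweenness Centralization"
        },
        "degree_centralization": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Degree Centralization"
        },
        "in_degree_centralization": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "In Degree Centralization"
        },
        "n_edges": {
          "title": "N Edges",
          "type": "integer"
        },
        "n_isolates": {
          "title": "N Isolates",
          "type": "integer"
        },
        "n_nodes": {
          "title": "N Nodes",
          "type": "integer"
        },
        "out_degree_centralization": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Out Degree Centralization"
        },
        "total_degree_centralization": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Total Degree Centralization"
        },
        "total_degree_mean": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Total Degree Mean"
        }
      },
      "required": [
        "n_nodes",
        "n_edges",
        "n_isolates",
        "average_degree"
      ],
      "title": "BundleNetworkStats",
      "type": "object"
    },
    "BundleNode": {
      "additionalProperties": false,
      "properties": {
        "agency_type": {
          "default": "",
          "title": "Agency Type",
          "type": "string"
        },
        "betweenness": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Betweenness"
        },
        "degree": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Degree"
        },
        "id": {
          "title": "Id",
          "type": "string"
        },
        "in_degree": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "In Degree"
        },
        "name": {
          "default": "",
          "title": "Name",
          "type": "string"
        },
        "out_degree": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Out Degree"
        },
        "vs_avg_betweenness": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Vs Avg Betweenness"
        },
        "vs_avg_degree": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Vs Avg Degree"
        },
        "vs_avg_in_degree": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Vs Avg In Degree"
        },
        "vs_avg_out_degree": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Vs Avg Out Degree"
        },
        "x": {
          "title": "X",
          "type": "number"
        },
        "y": {
          "title": "Y",
          "type": "number"
        }
      },
      "required": [
        "id",
        "x",
        "y"
      ],
      "title": "BundleNode",
      "type": "object"
    }
  },
  "$id": "https://example.org/collabnet/navigator_bundle/1.0",
  "additionalProperties": false,
  "properties": {
    "area_id": {
      "title": "Area Id",
      "type": "string"
    },
    "layers": {
      "items": {
        "$ref": "#/$defs/BundleLayer"
      },
      "title": "Layers",
      "type": "array"
    },
    "schema_version": {
      "title": "Schema Version",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    }
  },
  "required": [
    "schema_version",
    "area_id",
    "seed",
    "layers"
  ],
  "title": "NavigatorBundle",
  "type": "object"
}
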