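{
  "description": "Minimal structural schema for the tenascope pipeline report. Types: object/array/string/number/boolean/null; 'optional' fields may be null or absent.",
  "required": {
    "run": {
      "type": "object",
      "required": {
        "tool": "string",
        "version": "string",
        "seed": "number",
        "config_hash": "string",
        "n_proteins": "number",
        "n_tenascins": "number",
        "egf_mode": "string"
      }
    },
    "calls": {
      "type": "array",
      "item_required": {
        "protein_id": "string",
        "is_tenascin": "boolean",
        "final_label": "string",
        "reasons": "array"
      }
    },
    "inventory": {"type": "object"},
    "tree": {"type": ["string", "null"]},
    "synteny": {"type": "array"}
  }
}
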