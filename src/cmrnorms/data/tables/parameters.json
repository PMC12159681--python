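{
 "table_id": "parameters",
 "kind": "parameter_defs",
 "title": "Parameter registry: ids, units, BSA indexing and papillary-muscle convention"
}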