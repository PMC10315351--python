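{
  "version": "1",
  "comment": "Default capping groups: neutral, apolar, hydrogen-only. Each group bonds directly to the dangling atom and fills 'fill' units of open valence. Richer caps (e.g. methyl) can be added per element without code changes.",
  "elements": {
    "*": [
      {"name": "hydrogen", "fill": 1, "atoms": [{"element": "H", "order": 1}]}
    ]
  }
}
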