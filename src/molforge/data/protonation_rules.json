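{
  "_comment": "Each rule: SMARTS pattern, index of the (de)protonatable atom within the match, and the list of (formal charge, hydrogen delta) states the site can adopt. delta_h is relative to the neutral form matched by the pattern.",
  "rules": [
    {
      "name": "carboxylic_acid",
      "smarts": "[CX3](=O)[OX2H1]",
      "atom": 2,
      "states": [{"charge": 0, "delta_h": 0}, {"charge": -1, "delta_h": -1}]
    },
    {
      "name": "thiol",
      "smarts": "[SX2H1;!$([S][S])]",
      "atom": 0,
      "states": [{"charge": 0, "delta_h": 0}, {"charge": -1, "delta_h": -1}]
    },
    {
      "name": "selenol",
      "smarts": "[SeX2H1]",
      "atom": 0,
      "states": [{"charge": 0, "delta_h": 0}, {"charge": -1, "delta_h": -1}]
    },
    {
      "name": "phenol",
      "smarts": "[c][OX2H1]",
      "atom": 1,
      "states": [{"charge": 0, "delta_h": 0}, {"charge": -1, "delta_h": -1}]
    },
    {
      "name": "amine",
      "smarts": "[NX3;!$([N]C=[O,S,N]);!$([N]S=O);!$([N]a)]",
      "atom": 0,
      "states": [{"charge": 0, "delta_h": 0}, {"charge": 1, "delta_h": 1}]
    }
  ]
}
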