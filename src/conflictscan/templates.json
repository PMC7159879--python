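[
  {
    "name": "VMAP",
    "required": ["VMAP", "MoxR", "vWA"],
    "optional": ["Trypco1", "Trypco2", "ABhydrolase"],
    "anchor_role": "vWA",
    "effector_role": "vWA",
    "core_domain": "vWA",
    "comment": "classical ternary system: VMAP gene, then MoxR, then vWA 5'->3'; effectors are C-terminal fusions on the vWA component"
  },
  {
    "name": "iSTAND",
    "required": ["MoxR", "vWA", "iSTAND"],
    "anchor_role": "vWA",
    "effector_role": "vWA",
    "core_domain": "vWA",
    "comment": "ternary system with a catalytically inactive STAND NTPase third component"
  },
  {
    "name": "FtsH",
    "required": ["MoxR", "vWA", "FtsH"],
    "anchor_role": "vWA",
    "effector_role": "vWA",
    "core_domain": "vWA"
  },
  {
    "name": "BetaPropeller",
    "required": ["MoxR", "vWA", "BetaPropeller"],
    "anchor_role": "vWA",
    "effector_role": "vWA",
    "core_domain": "vWA",
    "comment": "beta-propeller fused to the vWA component; the fusion satisfies both roles on one gene"
  },
  {
    "name": "GAP1-N1",
    "required": ["DO-GTPase", "GAP1-N1", "GASH"],
    "optional": ["DO-GTPase"],
    "anchor_role": "GAP1-N1",
    "effector_role": "GAP1-N1",
    "core_domain": "GAP1-N1",
    "comment": "GTPase-centric system, subtype 1; a paralogous second DO-GTPase gene is optional"
  },
  {
    "name": "GAP1-N2",
    "required": ["DO-GTPase", "GAP1-N2", "FNIII"],
    "anchor_role": "GAP1-N2",
    "effector_role": "GAP1-N2",
    "core_domain": "GAP1-N2"
  },
  {
    "name": "NucA",
    "required": ["NucA", "Trypsin"],
    "anchor_role": "NucA",
    "effector_role": "NucA",
    "core_domain": "NucA"
  },
  {
    "name": "EACC1",
    "required": ["EACC1", "Caspase"],
    "anchor_role": "EACC1",
    "effector_role": "Caspase",
    "core_domain": "Caspase",
    "comment": "membrane-anchored constant component followed by a caspase-fused partner gene"
  }
]
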