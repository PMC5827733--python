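[
 {"reaction_id": "XEN_NAT2_INH", "template": "acetylation", "location": "cytosol",
  "roles": {"AcCoA": "AcCoA", "CoA": "CoA"},
  "note": "NAT2 acetylation: isoniazid -> acetylisoniazid"},
 {"reaction_id": "XEN_NAT2_HZ", "template": "acetylation", "location": "cytosol",
  "roles": {"AcCoA": "AcCoA", "CoA": "CoA"},
  "note": "NAT2 acetylation: hydrazine -> acetylhydrazine"},
 {"reaction_id": "XEN_NAT2_ACHZ", "template": "acetylation", "location": "cytosol",
  "roles": {"AcCoA": "AcCoA", "CoA": "CoA"},
  "note": "NAT2 acetylation: acetylhydrazine -> diacetylhydrazine"},
 {"reaction_id": "XEN_AMIDASE_INH", "template": "hydrolysis", "location": "cytosol",
  "roles": {"H2O": "H2O"},
  "note": "amidase hydrolysis: isoniazid -> isonicotinic acid + hydrazine"},
 {"reaction_id": "XEN_AMIDASE_ACINH", "template": "hydrolysis", "location": "cytosol",
  "roles": {"H2O": "H2O"},
  "note": "amidase hydrolysis: acetylisoniazid -> isonicotinic acid + acetylhydrazine"},
 {"reaction_id": "XEN_CYP2E1_ACHZ", "template": "oxidation_nadph", "location": "cytosol",
  "roles": {"O2": "O2", "NADPH": "NADPH", "NADP": "NADP"},
  "note": "CYP2E1 oxidation of acetylhydrazine (NADPH-dependent monooxygenase)"},
 {"reaction_id": "XEN_GLYCONJ_INA", "template": "aa_conjugation", "location": "mitochondria",
  "roles": {"AA": "glycine"},
  "note": "glycine conjugation: isonicotinic acid -> isonicotinoyl glycine"},
 {"reaction_id": "XEN_NOS2_HZ", "template": "oxidation", "location": "cytosol",
  "roles": {"O2": "O2"},
  "note": "NOS2-mediated hepatic hydrazine clearance (oxidation)"}
]
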