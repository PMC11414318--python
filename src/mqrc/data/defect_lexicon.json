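{
  "format": "mqrc-defect-lexicon",
  "version": 1,
  "comment": "Controlled defect terms for suspected medicine quality defects in oral and related dosage forms. applicable_forms uses the dosage_form vocabulary, or [\"all\"] for terms eligible in every dosage form. synonyms are case-insensitive trigger phrases matched as substrings of the complaint text.",
  "terms": [
    {
      "name": "caking",
      "applicable_forms": ["oral_liquid"],
      "cause_class": "environmental_degradation",
      "synonyms": ["caking", "solid lumps", "clumped into masses", "agglomeration"]
    },
    {
      "name": "capping_lamination",
      "applicable_forms": ["tablet"],
      "cause_class": "poor_manufacturing_practice",
      "synonyms": ["capping", "lamination", "separated into layers", "split into layers"]
    },
    {
      "name": "chipping_breaking",
      "applicable_forms": ["tablet"],
      "cause_class": "poor_manufacturing_practice",
      "synonyms": ["chipped", "broken tablets", "edge breakage", "tablet breaking"]
    },
    {
      "name": "cracking",
      "applicable_forms": ["tablet"],
      "cause_class": "poor_manufacturing_practice",
      "synonyms": ["cracked", "cracking", "fissures on the surface"]
    },
    {
      "name": "incomplete_package",
      "applicable_forms": ["tablet", "capsule"],
      "cause_class": "poor_manufacturing_practice",
      "synonyms": ["incomplete pack", "empty blister", "missing dose unit", "missing tablets in blister"]
    },
    {
      "name": "leakage",
      "applicable_forms": ["oral_liquid", "injection"],
      "cause_class": "poor_manufacturing_practice",
      "synonyms": ["leakage", "leaking", "outflow of contents", "contents leaked"]
    },
    {
      "name": "mislabelling",
      "applicable_forms": ["all"],
      "cause_class": "poor_manufacturing_practice",
      "synonyms": ["mislabelling", "mislabelled", "wrong label", "incorrect label", "labelling error", "illegible label"]
    },
    {
      "name": "mottling_colour_change",
      "applicable_forms": ["tablet", "capsule", "oral_liquid"],
      "cause_class": "both",
      "synonyms": ["mottling", "colour change", "color change", "discoloured", "discolored", "uneven colour"]
    },
    {
      "name": "moulding",
      "applicable_forms": ["tablet", "capsule", "oral_liquid"],
      "cause_class": "both",
      "synonyms": ["moulding", "mould growth", "mold growth", "microbial spoilage", "mouldy"]
    },
    {
      "name": "odour_change",
      "applicable_forms": ["all"],
      "cause_class": "environmental_degradation",
      "synonyms": ["odour change", "unusual smell", "unpleasant smell", "strange odour", "unusual gas"]
    },
    {
      "name": "phase_inversion",
      "applicable_forms": ["oral_liquid"],
      "cause_class": "environmental_degradation",
      "synonyms": ["phase inversion", "phase separation", "separated into phases", "emulsion split"]
    },
    {
      "name": "powdering",
      "applicable_forms": ["tablet"],
      "cause_class": "poor_manufacturing_practice",
      "synonyms": ["powdering", "crumbling to powder", "eroding on shaking", "turned to powder"]
    },
    {
      "name": "sticking_picking_binding",
      "applicable_forms": ["tablet", "capsule", "oral_liquid"],
      "cause_class": "poor_manufacturing_practice",
      "synonyms": ["sticking", "stuck to the package", "picking", "glued to the blister"]
    },
    {
      "name": "taste_change",
      "applicable_forms": ["all"],
      "cause_class": "environmental_degradation",
      "synonyms": ["taste change", "unusual taste", "unpleasant taste", "abnormal taste"]
    },
    {
      "name": "uneven_splitting",
      "applicable_forms": ["tablet"],
      "cause_class": "poor_manufacturing_practice",
      "synonyms": ["uneven splitting", "irregular breaking at the score", "splits unevenly"]
    },
    {
      "name": "unusual_stains_spots",
      "applicable_forms": ["tablet", "capsule", "oral_liquid"],
      "cause_class": "poor_manufacturing_practice",
      "synonyms": ["unusual stains", "dark spots", "light spots", "smudges on the surface", "unusual spots"]
    },
    {
      "name": "other_quality_defect",
      "applicable_forms": ["all"],
      "cause_class": "both",
      "synonyms": ["quality defect", "physical defect", "foreign particles", "packaging defect", "damaged packaging", "product instability"]
    }
  ]
}
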