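{
  "_comment": "Element catalogue: homologous antler elements (tines, beams, processes). 'parent' is the element an element branches from ('base' = antler base at the burr); 'placement' is 'terminal' when the element arises at the terminal fork of its parent (consuming the parent's tip) and 'lateral' when it branches from the side of the parent. 'requires' lists structural prerequisites. Pocock legacy codes are informational; the same legacy code can map to non-homologous elements in different clades.",
  "elements": [
    {"code": "B",    "name": "brow tine",                    "category": "tine",    "pocock_code": "a1", "parent": "base", "placement": "terminal"},
    {"code": "L",    "name": "lower beam",                   "category": "beam",    "pocock_code": "p1", "parent": "base", "placement": "terminal"},
    {"code": "T",    "name": "trez tine",                    "category": "tine",    "pocock_code": "a2", "parent": "L",    "placement": "terminal"},
    {"code": "H",    "name": "higher beam",                  "category": "beam",    "pocock_code": "p2", "parent": "L",    "placement": "terminal"},
    {"code": "F",    "name": "frontal tine",                 "category": "tine",    "pocock_code": "a2", "parent": "L",    "placement": "terminal"},
    {"code": "U",    "name": "upper beam",                   "category": "beam",    "pocock_code": "p2", "parent": "L",    "placement": "terminal"},
    {"code": "V",    "name": "vertical beam",                "category": "beam",    "pocock_code": "a2", "parent": "L",    "placement": "terminal"},
    {"code": "K",    "name": "back beam",                    "category": "beam",    "pocock_code": "p2", "parent": "L",    "placement": "terminal"},
    {"code": "Z",    "name": "bez tine",                     "category": "tine",    "pocock_code": null, "parent": "L",    "placement": "lateral"},
    {"code": "M",    "name": "medial tine",                  "category": "tine",    "pocock_code": "p2", "parent": "L",    "placement": "lateral"},
    {"code": "BWP",  "name": "brow process",                 "category": "process", "pocock_code": null, "parent": "L",    "placement": "lateral"},
    {"code": "BI",   "name": "brow-inner tine",              "category": "tine",    "pocock_code": null, "parent": "B",    "placement": "terminal"},
    {"code": "BO",   "name": "brow-outer tine",              "category": "tine",    "pocock_code": null, "parent": "B",    "placement": "terminal"},
    {"code": "CI",   "name": "crown-inner tine",             "category": "tine",    "pocock_code": null, "parent": "H",    "placement": "terminal"},
    {"code": "CO",   "name": "crown-outer tine",             "category": "tine",    "pocock_code": null, "parent": "H",    "placement": "terminal"},
    {"code": "CB",   "name": "crown-back tine",              "category": "tine",    "pocock_code": null, "parent": "H",    "placement": "terminal"},
    {"code": "CBI",  "name": "crown-back-inner tine",        "category": "tine",    "pocock_code": null, "parent": "CB",   "placement": "terminal"},
    {"code": "CBB",  "name": "crown-back-back tine",         "category": "tine",    "pocock_code": null, "parent": "CB",   "placement": "terminal"},
    {"code": "C",    "name": "cacuminal tine",               "category": "tine",    "pocock_code": null, "parent": "H",    "placement": "terminal"},
    {"code": "PCs",  "name": "pre-cacuminal tines",          "category": "tine",    "pocock_code": null, "parent": "H",    "placement": "lateral"},
    {"code": "G",    "name": "guard tine",                   "category": "tine",    "pocock_code": null, "parent": "H",    "placement": "lateral"},
    {"code": "TA",   "name": "terminal-anterior tine",       "category": "tine",    "pocock_code": null, "parent": "U",    "placement": "terminal"},
    {"code": "TP",   "name": "terminal-posterior tine",      "category": "tine",    "pocock_code": null, "parent": "U",    "placement": "terminal"},
    {"code": "TPAs", "name": "terminal-posterior-anterior tines", "category": "tine", "pocock_code": null, "parent": "TP", "placement": "lateral"},
    {"code": "R",    "name": "rear tine",                    "category": "tine",    "pocock_code": "p3", "parent": "U",    "placement": "lateral"},
    {"code": "U1",   "name": "upper-1st tine",               "category": "tine",    "pocock_code": null, "parent": "U",    "placement": "lateral"},
    {"code": "U1A",  "name": "upper-1st-anterior tine",      "category": "tine",    "pocock_code": null, "parent": "U1",   "placement": "terminal"},
    {"code": "U1P",  "name": "upper-1st-posterior tine",     "category": "tine",    "pocock_code": null, "parent": "U1",   "placement": "terminal"},
    {"code": "U2",   "name": "upper-2nd tine",               "category": "tine",    "pocock_code": null, "parent": "U",    "placement": "lateral"},
    {"code": "U3",   "name": "upper-3rd tine",               "category": "tine",    "pocock_code": null, "parent": "U",    "placement": "lateral"},
    {"code": "FPs",  "name": "frontal-posterior tines",      "category": "tine",    "pocock_code": null, "parent": "F",    "placement": "lateral"},
    {"code": "K1",   "name": "back-first tine",              "category": "tine",    "pocock_code": null, "parent": "K",    "placement": "lateral"},
    {"code": "V1",   "name": "vertical-first tine",          "category": "tine",    "pocock_code": null, "parent": "V",    "placement": "lateral"}
  ]
}
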