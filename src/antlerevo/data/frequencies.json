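{
  "_comment": "Species-level element frequencies. Entries are percentages in [0,100] or qualitative tokens (all, almost_all, common, rare, very_rare, absent). Numeric values come from explicit percentages in the text (medial tine 100/11, pre-cacuminal tines 40/33, trez present in 6% of Elaphurus = 100-94 loss); qualitative tokens paraphrase 'observed in almost all specimens', 'rarely', 'very rarely'. Unlisted (species, element) pairs are absent. This registry is a curated approximation of the per-species percentage table; it is exact at the level of the coded states {0,1,2}.",
  "frequencies": {
    "Alces alces":            {"L": "all", "U": "all", "TA": "almost_all", "TP": "almost_all", "TPAs": "common"},
    "Axis axis":              {"L": "all", "B": "almost_all", "T": "almost_all", "H": "almost_all", "BWP": "common"},
    "Axis porcinus":          {"L": "all", "B": "almost_all", "T": "almost_all", "H": "almost_all", "BWP": "common"},
    "Blastocerus dichotomus": {"L": "all", "F": "almost_all", "U": "almost_all", "R": "almost_all"},
    "Capreolus capreolus":    {"L": "all", "B": "almost_all", "F": "almost_all", "U": "almost_all"},
    "Capreolus pygargus":     {"L": "all", "B": "almost_all", "F": "almost_all", "U": "almost_all"},
    "Cervus canadensis":      {"L": "all", "B": "almost_all", "T": "almost_all", "H": "almost_all", "BWP": "common", "Z": "all", "CI": "almost_all", "CB": "almost_all", "CBI": "almost_all", "CBB": "almost_all", "CO": "very_rare"},
    "Cervus elaphus":         {"L": "all", "B": "almost_all", "T": "almost_all", "H": "almost_all", "BWP": "common", "Z": "all", "CI": "almost_all", "CO": "almost_all", "CB": "almost_all", "CBI": "common", "CBB": "common"},
    "Cervus nippon":          {"L": "all", "B": "almost_all", "T": "almost_all", "H": "almost_all", "BWP": "common", "CI": "almost_all", "CO": "almost_all", "CB": "rare"},
    "Dama dama":              {"L": "all", "B": "almost_all", "T": "almost_all", "H": "almost_all", "BWP": "common", "Z": "rare", "CI": "common", "CO": "rare", "CB": "common", "G": "almost_all"},
    "Elaphodus cephalophus":  {"L": "all"},
    "Elaphurus davidianus":   {"L": "all", "B": "almost_all", "T": 6, "H": "almost_all", "BWP": "common", "M": 11, "PCs": 33, "BI": "almost_all", "BO": "almost_all"},
    "Hydropotes inermis":     {},
    "Mazama americana":       {"L": "all"},
    "Muntiacus muntjak":      {"L": "all", "B": "almost_all"},
    "Muntiacus reevesi":      {"L": "all", "B": "almost_all"},
    "Odocoileus hemionus":    {"L": "all", "B": "rare", "F": "very_rare", "U": "all", "R": "almost_all", "U1": "almost_all", "U1A": "common", "U1P": "common", "U2": "almost_all", "U3": "common"},
    "Odocoileus virginianus": {"L": "all", "B": "rare", "F": "very_rare", "U": "all", "R": "almost_all", "U1": "almost_all", "U1A": "common", "U1P": "common", "U2": "almost_all", "U3": "common"},
    "Panolia eldii":          {"L": "all", "B": "almost_all", "H": "almost_all", "BWP": "common", "M": 100, "PCs": 40, "C": "almost_all"},
    "Rangifer tarandus":      {"L": "all", "B": "almost_all", "F": "almost_all", "U": "almost_all", "FPs": "common", "R": "almost_all", "TA": "common", "TP": "common"},
    "Rucervus duvaucelii":    {"L": "all", "B": "almost_all", "V": "almost_all", "K": "almost_all", "K1": "common", "V1": "common"},
    "Rucervus schomburgki":   {"L": "all", "B": "almost_all", "V": "almost_all", "K": "almost_all", "K1": "common", "V1": "common"},
    "Rusa marianna":          {"L": "all", "B": "almost_all", "T": "almost_all", "H": "almost_all", "BWP": "common"},
    "Rusa timorensis":        {"L": "all", "B": "almost_all", "T": "almost_all", "H": "almost_all", "BWP": "common"},
    "Rusa unicolor":          {"L": "all", "B": "almost_all", "T": "almost_all", "H": "almost_all", "BWP": "common", "Z": "rare", "CI": "rare"}
  }
}
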