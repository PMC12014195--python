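{
  "description": "Default Fitzpatrick Skin Type reference palette. Representative sRGB swatches for FST I (lightest) through VI (darkest), chosen so that each swatch's own Individual Typology Angle falls inside its own del Bino ITA band (boundaries 55, 41, 28, 10, -30 degrees) and adjacent classes are separated by at least 11 CIE76 units. Replace with a study-specific palette (JSON or palette photograph) for calibrated work.",
  "space": "srgb",
  "colors": [
    {"fst": 1, "rgb": [244, 208, 177]},
    {"fst": 2, "rgb": [231, 180, 143]},
    {"fst": 3, "rgb": [210, 152, 108]},
    {"fst": 4, "rgb": [187, 119, 80]},
    {"fst": 5, "rgb": [133, 80, 52]},
    {"fst": 6, "rgb": [64, 32, 21]}
  ]
}
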