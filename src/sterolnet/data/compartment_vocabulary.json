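{
  "terms": [
    "endoplasmic reticulum membrane",
    "golgi apparatus membrane",
    "plasma membrane",
    "nucleus inner membrane",
    "mitochondrion outer membrane",
    "cytoplasmic vesicle membrane",
    "cytoplasmic vesicle",
    "cytosol",
    "nucleus",
    "nucleoplasm",
    "peroxisome",
    "lipid droplet",
    "mitochondrion",
    "extracellular space",
    "endosome"
  ],
  "synonyms": {
    "erm": "endoplasmic reticulum membrane",
    "er membrane": "endoplasmic reticulum membrane",
    "gam": "golgi apparatus membrane",
    "golgi membrane": "golgi apparatus membrane",
    "pm": "plasma membrane",
    "nim": "nucleus inner membrane",
    "inner nuclear membrane": "nucleus inner membrane",
    "ld": "lipid droplet",
    "lipid droplets": "lipid droplet",
    "peroxisomes": "peroxisome"
  }
}
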