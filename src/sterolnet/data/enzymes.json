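{
  "enzymes": [
    "HMGCR", "MVK", "PMVK", "MVD", "FDPS", "FDFT1", "SQLE", "LSS",
    "DHCR24", "CYP51A1", "TM7SF2", "MSMO1", "NSDHL", "HSD17B7",
    "EBP", "SC5D", "DHCR7"
  ]
}
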