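# Compartment profiles of the 17 cholesterol-synthesis enzymes
# (NextProt-style terms; soluble enzymes: MVK, PMVK, MVD, FDPS, LSS)
HMGCR	endoplasmic reticulum membrane;peroxisome
MVK	cytosol
PMVK	cytosol;peroxisome
MVD	cytosol;peroxisome
FDPS	cytosol;lipid droplet
FDFT1	endoplasmic reticulum membrane
SQLE	endoplasmic reticulum membrane
LSS	cytosol;peroxisome;lipid droplet
DHCR24	endoplasmic reticulum membrane;golgi apparatus membrane
CYP51A1	endoplasmic reticulum membrane
TM7SF2	endoplasmic reticulum membrane;nucleus inner membrane
MSMO1	endoplasmic reticulum membrane
NSDHL	endoplasmic reticulum membrane;lipid droplet
HSD17B7	endoplasmic reticulum membrane
EBP	endoplasmic reticulum membrane;nucleus inner membrane
SC5D	endoplasmic reticulum membrane
DHCR7	endoplasmic reticulum membrane;cytoplasmic vesicle
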