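# Curated modifying-protein class map.  The "core" tier lists partners
# described in the primary literature as modifying the cholesterol
# synthesis enzymes; the "extended" tier carries further family members.
symbol	class	tier
PRKAA1	protein_kinase	core
PRKACA	protein_kinase	core
MAP2K5	protein_kinase	core
GSK3B	protein_kinase	core
PRKCA	protein_kinase	core
ILK	protein_kinase	extended
KSR1	protein_kinase	extended
PPP2CA	protein_phosphatase	core
PPP1CB	protein_phosphatase	extended
DUSP6	protein_phosphatase	extended
PTPN5	protein_phosphatase	extended
PTPN1	protein_phosphatase	extended
AMFR	ubiquitin_ligase	core
MARCHF6	ubiquitin_ligase	core
RNF145	ubiquitin_ligase	core
MYLIP	ubiquitin_ligase	core
ITCH	ubiquitin_ligase	core
SYVN1	ubiquitin_ligase	core
USP20	deubiquitinase	core
CYLD	deubiquitinase	extended
CTSL	protease	core
CASP7	protease	extended
CAPN1	protease	extended
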