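gene	pathway	mirnas	lncrnas	circrnas
COMP	PI3K-Akt signaling pathway	miR-211-z	ENSGALT00000102650
FN1	Pathways in cancer	miR-9-x	ENSGALT00000069126, ENSGALT00000097813, ENSGALT00000099218, ENSGALT00000103601, MSTRG.10467.1	novel_circ_010071
ITGA8	PI3K-Akt signaling pathway	miR-4324-z	ENSGALT00000103728, ENSGALT00000105373, MSTRG.19817.1	novel_circ_015884
THBS1	PI3K-Akt signaling pathway	gga-miR-155, miR-155-x, miR-211-z	ENSGLT0000055899, ENSGALT00000093080, ENSGALT00000097500, ENSGALT00000098724, ENSGALT00000100307, MSTRG.12108.4, MSTRG.18017.1, MSTRG.2399.1, MSTRG.2955.5, MSTRG.3306.4, MSTRG.8753.4	novel_circ_013543, novel_circ_013544, novel_circ_013545, novel_circ_014674
TNC	PI3K-Akt signaling pathway	miR-9-x	ENSGALT00000069126, ENSGALT00000086733, ENSGALT00000097813, ENSGALT00000099218, MSTRG.10467.1	novel_circ_010071
IL8	Pathways in cancer	miR-6573-y	ENSGALT00000095578
CR1	Tuberculosis	gga-miR-143-5p	MSTRG.12254.4
PF4	Pathways in cancer	novel-m0022-5p, novel-m0023-3p	ENSGALT00000094510, ENSGALT00000097728, ENSGALT00000098801, ENSGALT00000105534, ENSGALT00000107766, MSTRG.16216.1, MSTRG.2592.2, MSTRG.5783.5
MAPK10	Pathways in cancer	gga-miR-1677-3p, gga-miR-489-3p, novel-m0012-3p, gga-miR-133a-5p, gga-miR-205a, gga-miR-365-3p, miR-205-z, novel-m0082-3p, gga-miR-1625-5p, novel-m0031-5p	ENSGALT00000092815, ENSGALT00000097073, MSTRG.13979.1, MSTRG.4262.1
AGT	Pathways in cancer	gga-miR-1551-5p, gga-miR-365-3p	ENSGALT00000091177, ENSGALT00000102866, MSTRG.16427.1, MSTRG.3924.2, MSTRG.5783.5
COL3A1	Amoebiasis	miR-9-x	ENSGALT00000069126, ENSGALT00000086733, ENSGALT00000097813, ENSGALT00000099218, ENSGALT00000103601, ENSGALT00000106808, MSTRG.10467.1	novel_circ_010071
SMAD2Z	Pathways in cancer	gga-miR-155, miR-155-x	ENSGALT00000092121, ENSGALT00000097500, MSTRG.18017.1, MSTRG.2399.1, MSTRG.6929.1	novel_circ_006786, novel_circ_014674
MYLK	Calcium signaling pathway	gga-miR-1682, miR-1682-z	ENSGALT00000034451, ENSGALT00000064614, ENSGALT00000098372, ENSGALT00000108215, MSTRG.18028.1, MSTRG.18747.5, MSTRG.19170.5, MSTRG.3306.4	novel_circ_014674
PDGFD	PI3K-Akt signaling pathway	gga-miR-1682, miR-1682-z, gga-miR-155, miR-155-x, miR-222-z, miR-9-x	ENSGALT00000055899, ENSGALT00000095958, ENSGALT00000097500, ENSGALT00000100860, MSTRG.18017.1, MSTRG.19170.5, MSTRG.3306.4	novel_circ_009336, novel_circ_013543, novel_circ_014674
F2	Pathways in cancer	novel-m0031-5p, novel-m0082-3p	MSTRG.14124.1, MSTRG.15941.1, MSTRG.4656.1	novel_circ_011083
KCNMB1	cGMP-PKG signaling pathway	miR-211-z, miR-9-x, gga-miR-1682, miR-1682-z, miR-155-x	ENSGALT00000029552, ENSGALT00000034451, ENSGALT00000095958, ENSGALT00000100307, ENSGALT00000108215, MSTRG.18028.1, MSTRG.18747.5, MSTRG.19170.5, MSTRG.3306.4 MSTRG.852.1 MSTRG.8753.4	novel_circ_009336, novel_circ_014674, novel_circ_018442
KCNMA1	cGMP-PKG signaling pathway	gga-miR-3529	ENSGALT00000098838	novel_circ_009470
ACTA2	Apelin signaling pathway	miR-9-x	ENSGALT00000069126, ENSGALT00000086733, ENSGALT00000097813, ENSGALT00000099218, ENSGALT00000103601, ENSGALT00000106808, MSTRG.10467.1	novel_circ_010071
GNAQ	Pathways in cancer	miR-6552-x, miR-9-x		novel_circ_003034, novel_circ_017896
CXCR5	Cytokine-cytokine receptor interaction	gga-miR-143-5p, gga-miR-7442-5p	MSTRG.4518.5
CCR7	Cytokine-cytokine receptor interaction	gga-miR-12258-5p, novel-m0012-3p	MSTRG.5730.1, MSTRG.9716.2
CAMK2A	Pathways in cancer	gga-miR-143-5p	ENSGALT00000095677, MSTRG.12254.4
HTR2C	Neuroactive ligand-receptor interaction	novel-m0031-5p	ENSGALT00000092468
CYP2J2	Metabolic pathways	novel-m0012-3p	ENSGALT00000091079, ENSGALT00000103356
MMP9	Pathways in cancer	gga-miR-155, miR-155-x, miR-6573-y	ENSGALT00000055899, ENSGALT00000097500, ENSGALT00000098724, ENSGALT00000100307, MSTRG.12108.4, MSTRG.18017.1, MSTRG.2399.1, MSTRG.2955.5, MSTRG.3306.4, MSTRG.8753.4	novel_circ_003034
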