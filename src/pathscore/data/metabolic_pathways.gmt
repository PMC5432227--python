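Glycolysis	reconstructed gene set (core glycolytic enzymes)	HK1	HK2	HK3	GPI	PFKL	PFKM	PFKP	ALDOA	ALDOB	ALDOC	TPI1	GAPDH	PGK1	PGAM1	PGAM2	ENO1	ENO2	ENO3	PKM	PKLR
Gluconeogenesis	reconstructed gene set (gluconeogenic enzymes)	PC	PCK1	PCK2	FBP1	FBP2	G6PC1	G6PC2	G6PC3
Lactate generation	reconstructed gene set (lactate dehydrogenases and exporters)	LDHA	LDHB	LDHC	SLC16A1	SLC16A3
Pyruvate to Acetyl CoA	reconstructed gene set (pyruvate dehydrogenase complex and its regulators)	PDHA1	PDHB	DLAT	DLD	PDHX	PDK1	PDK2	PDK3	PDK4	PDP1	PDP2
TCA Cycle	reconstructed gene set (tricarboxylic acid cycle enzymes)	CS	ACO1	ACO2	IDH2	IDH3A	IDH3B	IDH3G	OGDH	DLST	SUCLA2	SUCLG1	SUCLG2	SDHA	SDHB	SDHC	SDHD	FH	MDH1	MDH2
Oxpho I Complex	reconstructed gene set (NADH:ubiquinone oxidoreductase subunits)	NDUFS1	NDUFS2	NDUFS3	NDUFS4	NDUFS7	NDUFS8	NDUFV1	NDUFV2	NDUFA1	NDUFA2	NDUFA9	NDUFB1	NDUFB2
Oxpho II Complex	reconstructed gene set (succinate dehydrogenase subunits)	SDHA	SDHB	SDHC	SDHD
Oxpho III Complex	reconstructed gene set (cytochrome bc1 complex subunits)	UQCRC1	UQCRC2	UQCRFS1	UQCRB	UQCRQ	UQCRH	UQCR10	UQCR11	CYC1
Oxpho IV Complex	reconstructed gene set (cytochrome c oxidase subunits)	COX4I1	COX5A	COX5B	COX6A1	COX6B1	COX6C	COX7A2	COX7B	COX7C	COX8A
Oxpho V Complex	reconstructed gene set (ATP synthase subunits)	ATP5F1A	ATP5F1B	ATP5F1C	ATP5F1D	ATP5F1E	ATP5PB	ATP5MC1	ATP5PD	ATP5PF	ATP5PO
Pentose Phosphate Pathway	reconstructed gene set (oxidative and non-oxidative PPP enzymes)	G6PD	PGLS	PGD	RPIA	RPE	TKT	TKTL1	TALDO1
One-carbon metabolism	reconstructed gene set (serine synthesis and folate cycle enzymes)	PHGDH	PSAT1	PSPH	SHMT1	SHMT2	MTHFD1	MTHFD1L	MTHFD2	MTHFR	MTR	MTRR	TYMS	DHFR	GART	ATIC	MAT2A	AHCY
Glutaminolysis	reconstructed gene set (glutamine catabolism enzymes)	GLS	GLS2	GLUD1	GLUD2	GOT1	GOT2	GPT	GPT2
Proline Synthesis	reconstructed gene set (proline biosynthesis enzymes)	ALDH18A1	PYCR1	PYCR2	PYCRL	OAT	GLUL
Proline Degradation	reconstructed gene set (proline catabolism enzymes)	PRODH	PRODH2	ALDH4A1	OAT
Fatty Acid Activation	reconstructed gene set (acyl-CoA synthetases and fatty acid transporters)	ACSL1	ACSL3	ACSL4	ACSL5	ACSL6	ACSS1	ACSS2	SLC27A1	SLC27A2	SLC27A4
Fatty Acid B-oxidation	reconstructed gene set (mitochondrial beta-oxidation enzymes)	CPT1A	CPT1B	CPT2	SLC25A20	ACADVL	ACADL	ACADM	ACADS	ECHS1	HADHA	HADHB	ACAA2
Lipogenesis	reconstructed gene set (de novo fatty acid synthesis enzymes)	ACLY	ACACA	ACACB	FASN	SCD	ELOVL5	ELOVL6	ACSS2
Cholesterogenesis	reconstructed gene set (mevalonate and sterol synthesis enzymes)	HMGCS1	HMGCR	MVK	PMVK	MVD	IDI1	FDPS	FDFT1	SQLE	LSS	DHCR7	DHCR24
Ketogenesis	reconstructed gene set (ketone body synthesis enzymes)	ACAT1	HMGCS2	HMGCL	HMGCLL1	BDH1	BDH2
Ketolysis	reconstructed gene set (ketone body utilisation enzymes)	OXCT1	OXCT2	BDH1	BDH2	ACAT1
Choline_PhosphoCholine	reconstructed gene set (choline uptake and phosphorylation)	CHKA	CHKB	SLC44A1	SLC44A2	SLC5A7	PLD1	PLD2
CDP-Choline	reconstructed gene set (Kennedy pathway enzymes)	PCYT1A	PCYT1B	CHPT1	CEPT1
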