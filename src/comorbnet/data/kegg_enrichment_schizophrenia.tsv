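pathway	p	p_bh	genes
Neuroactive ligand-receptor interaction	3.29e-20	3.09e-18	ADRA1A,CCKAR,CHRM5,CHRNA7,CHRNB2,CNR1,DRD1,DRD2,DRD3,DRD4,DRD5,GABBR1,GABRA1,GABRA6,GABRB2,GABRG2,GABRP,GRIA1,GRIA3,GRIA4,GRID1,GRIK2,GRIK3,GRIK4,GRIN1,GRIN2A,GRIN2B,GRIN2D,GRM3,GRM4,GRM5,GRM7,GRM8,HRH1,HRH2,HTR1A,HTR2A,HTR2C,HTR4,HTR5A,HTR6,HTR7,MCHR1,TAAR6
Dopaminergic synapse	1.01e-15	4.73e-14	AKT1,ATF6B,CLOCK,COMT,DRD1,DRD2,DRD3,DRD4,DRD5,GNAL,GNAO1,GNAS,GNB3,GRIA1,GRIA3,GRIA4,GRIN2A,GRIN2B,GSK3B,MAOA,PPP1R1B,PPP2R2B,PPP3CC,SLC18A1,SLC18A2,SLC6A3,TH
Cocaine addiction	3.06e-14	9.59e-13	ATF6B,BDNF,DRD1,DRD2,GNAS,GRIN1,GRIN2A,GRIN2B,GRIN2D,GRM3,MAOA,PDYN,PPP1R1B,SLC18A1,SLC18A2,SLC6A3,TH
Amphetamine addiction	5.97e-14	1.40e-12	ATF6B,DRD1,GNAS,GRIA1,GRIA3,GRIA4,GRIN1,GRIN2A,GRIN2B,GRIN2D,MAOA,PDYN,PPP1R1B,PPP3CC,SLC18A1,SLC18A2,SLC6A3,STX1A,TH
Glutamatergic synapse	3.52e-13	6.61e-12	GNAO1,GNAS,GNB3,GRIA1,GRIA3,GRIA4,GRIK2,GRIK3,GRIK4,GRIN1,GRIN2A,GRIN2B,GRIN2D,GRM3,GRM4,GRM5,GRM7,GRM8,PLA2G4A,PLA2G4C,PPP3CC,SLC1A2,SLC1A6
Serotonergic synapse	2.09e-12	3.28e-11	CACNA1F,CYP2D6,GABRB2,GNAO1,GNAS,GNB3,HTR1A,HTR2A,HTR2C,HTR3A,HTR4,HTR5A,HTR6,HTR7,MAOA,PLA2G4A,PLA2G4C,PTGS2,SLC18A1,SLC18A2,SLC6A4,TPH1
Calcium signaling pathway	4.33e-12	5.81e-11	ADRA1A,CACNA1F,CCKAR,CD38,CHRM5,CHRNA7,DRD1,DRD5,EGFR,ERBB3,ERBB4,GNAL,GNAS,GRIN1,GRIN2A,GRIN2D,GRM5,HRH1,HRH2,HTR2A,HTR2C,HTR4,HTR5A,HTR6,HTR7,NOS1,PPP3CC
Nicotine addiction	5.38e-12	6.33e-11	CHRNA7,CHRNB2,GABRA1,GABRA6,GABRB2,GABRG2,GABRP,GRIA1,GRIA3,GRIA4,GRIN1,GRIN2A,GRIN2B,GRIN2D
cAMP signaling pathway	1.66e-7	1.73e-6	AKT1,BDNF,CACNA1F,DRD1,DRD2,DRD5,FXYD2,GABBR1,GNAS,GRIA1,GRIA3,GRIA4,GRIN1,GRIN2A,GRIN2B,GRIN2D,HTR1A,HTR4,HTR6,NPY,PDE4B,PPP1R1B
Alcoholism	2.45e-6	2.09e-5	ATF6B,BDNF,DRD1,DRD2,GNAO1,GNAS,GNB3,GRIN1,GRIN2A,GRIN2B,GRIN2D,MAOA,NPY,PDYN,PPP1R1B,SLC18A1,SLC18A2,SLC6A3,TH
Retrograde endocannabinoid signaling	2.24e-6	2.11e-5	CACNA1F,CNR1,GABRA1,GABRA6,GABRB2,GABRG2,GABRP,GNAO1,GNB3,GRIA1,GRIA3,GRIA4,GRM5,PTGS2
Circadian entrainment	6.03e-6	4.36e-5	GNAO1,GNAS,GNB3,GRIA1,GRIA3,GRIA4,GRIN1,GRIN2A,GRIN2B,GRIN2D,NOS1,NOS1AP,PER3
Rap1 signaling pathway	8.33e-5	4.61e-4	AKT1,CNR1,DRD2,EGF,EGFR,FGF1,FGF14,FGF18,FGFR1,GNAO1,GNAS,GRIN1,GRIN2A,GRIN2B,MAGI1,MAGI2,MAGI3,RAPGEF6
Morphine addiction	1.02e-4	5.33e-4	DRD1,GABBR1,GABRA1,GABRA6,GABRB2,GABRG2,GABRP,GNAO1,GNAS,GNB3,PDE4B
MAPK signaling pathway	1.09e-4	5.38e-4	AKT1,BDNF,CACNA1F,EGF,EGFR,FAS,FGF1,FGF14,FGF18,FGFR1,FLNB,IL1A,IL1B,MAPK8IP2,NTF3,PLA2G4A,PLA2G4C,PPP3CC,TNF,TP53
Cytokine-cytokine receptor interaction	1.84e-4	8.64e-4	CSF2RA,CSF2RB,CXCR1,EGF,EGFR,FAS,IL10,IL10RA,IL12B,IL18,IL18R1,IL18RAP,IL1A,IL1B,IL2,IL3,IL3RA,IL4,LTA,TNF
GABAergic synapse	3.52e-4	1.50e-3	CACNA1F,GABBR1,GABRA1,GABRA6,GABRB2,GABRG2,GABRP,GAD1,GNAO1,GNB3
PI3K-Akt signaling pathway	1.13e-3	4.19e-3	AKT1,ATF6B,EGF,EGFR,FGF1,FGF14,FGF18,FGFR1,FN1,GNB3,GSK3B,IL2,IL3,IL3RA,IL4,PPP2R2B,RELN,TNXB,TP53,YWHAE,YWHAH,YWHAZ
Phospholipase D signaling pathway	1.5e-3	4.53e-3	AKT1,CXCR1,EGF,EGFR,GNAS,GRM3,GRM4,GRM5,GRM7,GRM8,PLA2G4A,PLA2G4C
ErbB signaling pathway	1.37e-3	4.61e-3	AKT1,EGF,EGFR,ERBB3,ERBB4,GSK3B,NRG1,NRG2,NRG3
T cell receptor signaling pathway	1.33e-3	4.61e-3	AKT1,CD4,CTLA4,GSK3B,IL10,IL2,IL4,ITK,PPP3CC,TNF
Gap junction	1.49e-3	4.66e-3	DRD1,DRD2,EGF,EGFR,GNAS,GRM5,HTR2A,HTR2C,TUBA8
Long-term depression	2.34e-3	6.46e-3	GNAO1,GNAS,GRIA1,GRIA3,NOS1,PLA2G4A,PLA2G4C
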