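pathway	p	p_bh	genes
Neuroactive ligand-receptor interaction	4.19e-27	4.24e-25	ADRA2A,ADRB2,AGTR1,CHRM1,CHRM2,CHRM5,CHRNA1,CHRNA10,CHRNA2,CHRNA3,CHRNA4,CHRNA5,CHRNA6,CHRNA7,CHRNB1,CHRNB2,CHRNB3,CHRNB4,CHRND,CHRNG,CNR1,DRD1,DRD2,DRD3,DRD4,DRD5,GABBR1,GABBR2,GABRA2,GABRA4,GABRE,GALR1,GRIK1,GRIK2,GRIN1,GRIN2A,GRIN2B,GRIN3A,GRM7,HRH4,HTR1F,HTR2A,HTR6,NPY1R,NPY2R,NR3C1,OPRD1,OPRM1,PARD3
Cocaine addiction	2.10e-16	1.06e-14	BDNF,CREB1,CREB5,DDC,DLG4,DRD1,DRD2,GNAS,GRIN1,GRIN2A,GRIN2B,GRIN3A,MAOA,MAOB,PPP1R1B,SLC18A2,SLC6A3,TH
Dopaminergic synapse	4.12e-12	1.39e-10	ARRB2,COMT,CREB1,CREB5,DDC,DRD1,DRD2,DRD3,DRD4,DRD5,GNAS,GRIN2A,GRIN2B,ITPR2,KCNJ6,MAOA,MAOB,PPP1R1B,PPP2R2B,SLC18A2,SLC6A3,TH
cAMP signaling pathway	2.30e-11	4.64e-10	ABCC4,ADRB2,BDNF,CAMK4,CHRM1,CHRM2,CREB1,CREB5,DRD1,DRD2,DRD5,GABBR1,GABBR2,GNAS,GRIN1,GRIN2A,GRIN2B,GRIN3A,HTR1F,HTR6,NPY,NPY1R,PDE4D,PPP1R1B,RAPGEF3,RHOA
Amphetamine addiction	1.97e-11	4.97e-10	CAMK4,CREB1,CREB5,DDC,DRD1,GNAS,GRIN1,GRIN2A,GRIN2B,GRIN3A,MAOA,MAOB,PPP1R1B,SLC18A2,SLC6A3,TH
Chemical carcinogenesis	5.14e-11	8.65e-10	ADH1B,CHRNA7,CYP1A1,CYP1B1,CYP2A6,CYP2E1,EPHX1,GSTM1,GSTM3,GSTP1,GSTT1,NAT1,NAT2,PTGS2,SULT1A1,UGT1A7,UGT2B10
Drug metabolism	3.07e-9	4.42e-8	ADH1B,CYP2A6,CYP2B6,CYP2D6,CYP2E1,FMO1,GSTM1,GSTM3,GSTP1,GSTT1,MAOA,MAOB,UGT1A7,UGT2B10
Nicotine addiction	6.07e-9	7.67e-8	CHRNA4,CHRNA6,CHRNA7,CHRNB2,GABRA2,GABRA4,GABRE,GRIN1,GRIN2A,GRIN2B,GRIN3A
Metabolism of xenobiotics by cytochrome P450	9.81e-9	1.10e-7	ADH1B,CYP1A1,CYP1B1,CYP2A6,CYP2B6,CYP2D6,CYP2E1,EPHX1,GSTM1,GSTM3,GSTP1,GSTT1,UGT1A7,UGT2B10
Alcoholism	1.76e-8	1.77e-7	BDNF,CAMK4,CREB1,CREB5,DDC,DRD1,DRD2,GNAS,GRIN1,GRIN2A,GRIN2B,GRIN3A,MAOA,MAOB,NPY,NTRK2,PPP1R1B,SHC3,SLC18A2,SLC6A3,TH
Cholinergic synapse	4.92e-8	4.52e-7	CAMK4,CHAT,CHRM1,CHRM2,CHRM5,CHRNA3,CHRNA4,CHRNA6,CHRNA7,CHRNB2,CHRNB4,CREB1,CREB5,ITPR2,KCNJ6,KCNQ3
Serotonergic synapse	5.60e-8	4.72e-7	CYP2D6,DDC,GNAS,HTR1F,HTR2A,HTR6,ITPR2,KCNJ6,MAOA,MAOB,PTGS2,RAPGEF3,SLC18A2,SLC6A4,TPH1,TPH2
Morphine addiction	1.04e-6	8.05e-6	ARRB1,ARRB2,DRD1,GABBR1,GABBR2,GABRA2,GABRA4,GABRE,GNAS,KCNJ6,OPRM1,PDE1C,PDE4D
Calcium signaling pathway	1.81e-6	1.30e-5	ADRB2,AGTR1,CAMK4,CHRM1,CHRM2,CHRM5,CHRNA7,DRD1,DRD5,GNAS,GRIN1,GRIN2A,HTR2A,HTR6,ITPR2,NOS2,NOS3,PDE1C
Tryptophan metabolism	1.04e-5	7.03e-5	ALDH2,CYP1A1,CYP1B1,DDC,MAOA,MAOB,TPH1,TPH2
Glutamatergic synapse	1.34e-5	8.47e-5	DLG4,GNAS,GRIK1,GRIK2,GRIN1,GRIN2A,GRIN2B,GRIN3A,GRM7,HOMER1,HOMER2,ITPR2,SLC1A2
Tyrosine metabolism	3.80e-5	2.13e-4	ADH1B,COMT,DBH,DDC,MAOA,MAOB,TH
Estrogen signaling pathway	8.00e-5	4.25e-4	CREB1,CREB5,ESR1,GABBR1,GABBR2,GNAS,ITPR2,KCNJ6,NOS3,OPRM1,SHC3
Rap1 signaling pathway	6.87e-4	3.31e-3	CNR1,DRD2,FGF12,FGF14,GNAS,GRIN1,GRIN2A,GRIN2B,ITGB3,MAGI1,PARD3,RAPGEF3,RHOA,SIPA1L2,TEK
Steroid hormone biosynthesis	9.95e-4	4.37e-3	COMT,CYP17A1,CYP1A1,CYP1B1,CYP2E1,UGT1A7,UGT2B10
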