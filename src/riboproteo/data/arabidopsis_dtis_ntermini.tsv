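gene_locus	description	dtis	nterm
AT1G14610	Val-tRNA synthetase (TWN2)	Met45	Ac-S
AT1G29880	Gly-tRNA synthetase	Met40	Ac-MD
AT3G11710	Lys-tRNA synthetase (ATKRS-1)	Met17	Ac-MD
AT5G26830	Threonyl-tRNA synthetase (THRRS)	Met34	Ac-A
AT1G52160	tRNAse Z3 (TRZ3)	Met52	Ac-ME
AT2G45330	2' tRNA phosphotransferase	Met33	Ac-MD
AT1G06560	tRNA methyltransferase 4F (TRM4F)	Met37	Ac-ME
AT1G36310	tRNA methyltransferase 9 (TRM9)	Met29	NH2-MR
AT1G33060	NAC 014 (NAC014)	Met12	Ac-T
AT1G49480	Related to vernalization1 1 (RTV1)	Met3	Ac-MD
AT1G72210	Basic helix-loop-helix (bHLH96)	Met18	Ac-ME
AT4G22745	Methyl-CPG-binding domain 1 (MBD1)	Met7	NH2-MN
AT5G67220	BIM1	Met23	NH2-T
AT1G03360	Ribosomal RNA processing 4 (RRP4)	Met3	NH2-MR
AT1G07770;AT3G46040	Ribosomal protein S15A (RPS15A)	Thr105(ACG)->Met	NH2-T
AT1G18540;AT1G74050;AT1G74060	Ribosomal protein L6 family protein	Arg25(AGG)->Met	NH2-S
AT1G54270;AT3G13920	EIF4A-2	Arg52(AGG)->Met	NH2-G
AT1G71180	Probable 3-hydroxyisobutyrate dehydrogenase	Met22	Ac-ME
AT3G44310	Nitrilase 1 (NIT1)	Met7	Ac-S
AT1G58280	Phosphoglycerate mutase family protein	Met43	Ac-ME
AT3G60440	Phosphoglycerate mutase family protein	Met24	Ac-ME
AT5G16440	Isopentenyl diphosphate isomerase 1 (IPP1)	Met59	Ac-T
AT3G02780	Isopentenyl diphosphate isomerase 2 (IPP2)	Met52	Ac-T
AT4G37000	Accelerated cell death (ACD2)	Met41	Ac-ME
AT5G19150	NAD(P)HX dehydratase	Met45	Ac-S
AT5G24400	6-Phosphogluconolactonase 3 (PGL3)	Met70	Ac-A
AT5G36700	2-Phosphoglycolate phosphatase 1 (PGLP1)	Met54	Ac-T
AT3G56490	HIS triad family protein 3 (HIT3)	Met19	Ac-A
AT5G63890	Histidinol dehydrogenase (HDH)	Met18	NH2/Ac-MK
AT1G77670	Pyridoxal phosphate-dependent transferase	Met41	Ac-T
AT5G13050	5-Formyltetrahydrofolate cycloligase (5-FCL)	Met43	NH2/Ac-S
AT5G12040	omega-amidase	Met63	Ac-A
AT4G08790	Deaminated glutathione amidase	Met29	Ac-A
AT5G03370	Acylphosphatase family	Met66	NH2/Ac-T
AT5G15870	Glycosyl hydrolase family 81 protein	Met45	Ac-S
AT5G41970	Metal-dependent protein hydrolase	Met28	NH2-A
AT3G10620	Nudix hydrolase homolog 26 (NUDX26)	Met56	Ac-ME
AT1G43900	Protein phosphatase 2C family protein	Leu61(CTG)->Met	NH2/Ac-T
AT2G23070	Casein kinase II subunit alpha-4 (CKA4)	Leu85(CTG)->Met	Ac-A
AT4G08500	MAPK/ERK kinase kinase 1 (MEKK1)	Met8	Ac-MK
AT3G12200	NIMA-related kinase 7 (Nek7)	Met3	Ac-ME
AT5G11860	SCP1-like small phosphatase 5 (SSP5)	Met45	NH2/Ac-MK
AT2G30110	Ubiquitin-activating enzyme 1 (UBA1)	Met63	NH2/Ac-A
AT2G36170	Ubiquitin-60S ribosomal protein L40-1 (RPL40A)	Met84	NH2-ML
AT5G46210	Cullin4 (CUL4)	Met26	NH2/Ac-MK
AT2G45170	Autophagy 8E (ATG8E)	Met9	Ac-MD
AT4G30920	Leucine aminopeptidase 2 (LAP2)	Met57	NH2/Ac-A
AT1G76140	Prolyl endopeptidase	Met65	Ac-G
AT1G60950	Ferredoxin-2 (FD2)	Met52	NH2-A
AT2G17420	NADPH-dependent TRX reductase A (NTRA)	Met49	Ac-ME
AT4G19880	Glutathione S-transferase family protein	Met32	NH2/Ac-A
AT5G27380	Glutathione synthetase 2 (GSH2)	Met62	Ac-ME
AT2G47730	Glutathione S-transferase phi 8 (GSTF8)	Met49	Ac-A
AT4G11600	Glutathione peroxidase 6 (GPX6)	Met64	Ac-A
AT1G66240	Homolog of anti-oxidant 1 (ATX1)	Met31	Ac-S
AT1G55805	BolA-like family protein	Met52	Ac-S
AT3G23100	Homolog of X-ray repair cross complementing 4 (XRCC4)	Met17	NH2/Ac-V
AT2G19640	ASH1-related protein 2 (ASHR2)	Ile2(ATA)->Met	Ac-MN
AT5G61140	U5 small nuclear ribonucleoprotein helicase	Met72	NH2/Ac-ML
AT5G66675	Protein of unknown function (DUF677)	Met5	Ac-MF
AT5G14540	FLOE1	Met18	Ac-MD
AT3G27310	Plant UBX domain-containing protein 1 (PUX1)	Met22	Ac-ME
AT1G71840	WD-40 repeat family protein	Met10	Ac-MN
AT4G13940	Adenosylhomocysteinase 1 (SAHH)	Leu57(TTG)->Met	NH2-S
AT2G39080	NAD(P)-binding Rossmann-fold superfamily protein	Met59	Ac-A
AT2G43290	Calmodulin-like 5 (CML5)	Met47	Ac-ML
AT3G47590	Alpha/beta-Hydrolases superfamily protein	Met50	Ac-MD
AT1G53280	Protein DJ-1 homolog B (DJ1B)	Met48	Ac-S
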