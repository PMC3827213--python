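organism	accession	label	group
Synechococcus phage S-RSM4	YP_003097310.1	HspSP-RSM4	synechococcus_phage
Synechococcus phage S-PM2	YP_195165.1	HspSP-PM2	synechococcus_phage
Synechococcus phage S-SM1	YP_004323062.1	HspSP-SM1	synechococcus_phage
Synechococcus phage S-SSM5	YP_004324766.1	HspSP-SSM5	synechococcus_phage
Synechococcus phage Syn19	YP_004323990.1	HspSP-Syn19	synechococcus_phage
Synechococcus phage S-SM2	YP_004322303.1	HspSP-SM2	synechococcus_phage
Synechococcus phage S-CBM2	AFK66310.1	HspSP-CBM2	synechococcus_phage
Synechococcus phage S-MbCM6	YP_007001883.1	HspSP-MbCM6	synechococcus_phage
Synechococcus phage syn9	YP_717838.1	HspSP-Syn9	synechococcus_phage
Synechococcus phage metaG-MbCM1	YP_007001660.1	HspSP-MbCM1	synechococcus_phage
Synechococcus phage S-RIM8 A.HR1	YP_007518247.1	HspSP-RIM8	synechococcus_phage
Synechococcus phage S-ShM2	YP_004322832.1	HspSP-ShM2	synechococcus_phage
Synechococcus phage S-SSM7	YP_004324229.1	HspSP-SSM7	synechococcus_phage
Synechococcus phage S-CRM01	YP_004508578.1	HspSP-CRM01	synechococcus_phage
Synechococcus phage S-CAM8	AET72746.1	HspSP-CAM8	synechococcus_phage
Synechococcus phage S-RIM2 R1_1999	YP_007675621.1	HspSP-RIM2	synechococcus_phage
Synechococcus phage S-SKS1	YP_007674470.1	HspSP-SKS1	synechococcus_phage
Synechococcus phage S-CAM1	YP_007673074.1	HspSP-CAM1	synechococcus_phage
Synechococcus phage S-SSM4	YP_007677312.1	HspSP-SSM4	synechococcus_phage
Prochlorococcus phage Syn1	YP_004324522.1	HspPP-Syn1	prochlorococcus_phage
Prochlorococcus phage P-SSM4	YP_214702.1	HspPP-SSM4	prochlorococcus_phage
Prochlorococcus phage P-RSM4	YP_004323305.1	HspPP-RSM4	prochlorococcus_phage
Prochlorococcus phage Syn33	YP_004323772.1	HspPP-Syn33	prochlorococcus_phage
Prochlorococcus phage P-SSM2	YP_214406.1	HspPP-SSM2	prochlorococcus_phage
Prochlorococcus phage P-SSM7	YP_004325000.1	HspPP-SSM7	prochlorococcus_phage
Prochlorococcus phage P-HM2	YP_004323516.1	HspPP-HM2	prochlorococcus_phage
Prochlorococcus phage P-HM1	YP_004322573.1	HspPP-HM1	prochlorococcus_phage
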