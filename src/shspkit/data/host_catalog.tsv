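organism	accession	label	group	gene_count
Synechococcus sp. WH 5701	ZP_01083513.1	HspS-WH5701.1	synechococcus_host	3
Synechococcus sp. WH 5701	ZP_01084874.1	HspS-WH5701.2	synechococcus_host	3
Synechococcus sp. WH 5701	ZP_01086483.1	HspS-WH5701.3	synechococcus_host	3
Synechococcus sp. PCC 7335	ZP_05035247.1	HspS-PCC7335.1	synechococcus_host	3
Synechococcus sp. PCC 7335	ZP_05037140.1	HspS-PCC7335.2	synechococcus_host	3
Synechococcus sp. PCC 7335	ZP_05039268.1	HspS-PCC7335.3	synechococcus_host	3
Synechococcus sp. CB0101	ZP_07972696.1	HspS-CB0101.1	synechococcus_host	2
Synechococcus sp. CB0101	ZP_07973042.1	HspS-CB0101.2	synechococcus_host	2
Synechococcus sp. CB0205	ZP_07971592.1	HspS-CB0205.1	synechococcus_host	2
Synechococcus sp. CB0205	ZP_07969614.1	HspS-CB0205.2	synechococcus_host	2
Synechococcus sp. JA-3-3Ab	YP_474873.1	HspS-JA-3-3Ab.1	synechococcus_host	2
Synechococcus sp. JA-3-3Ab	YP_475298.1	HspS-JA-3-3Ab.2	synechococcus_host	2
Synechococcus sp. JA-2-3B'a(2-13)	YP_477816.1	HspS-JA-2-3B'a.1	synechococcus_host	2
Synechococcus sp. JA-2-3B'a(2-13)	YP_476514.1	HspS-JA-2-3B'a.2	synechococcus_host	2
Synechococcus sp. PCC 6312	YP_007061156.1	HspS-PCC6312	synechococcus_host	1
Synechococcus elongatus PCC 6301	YP_172414.1	HspS-PCC6301	synechococcus_host	1
Synechococcus sp. PCC 7502	YP_007106253.1	HspS-PCC7502	synechococcus_host	1
Synechococcus sp. PCC 7002	YP_001733915.1	HspS-PCC7002	synechococcus_host	1
Synechococcus sp. WH 7805	ZP_01125036.1	HspS-WH7805	synechococcus_host	1
Synechococcus sp. RCC307	YP_001228640.1	HspS-RCC307	synechococcus_host	1
Synechococcus sp. WH 7803	YP_001226126.1	HspS-WH7803	synechococcus_host	1
Synechococcus sp. PCC 7336	ALWC01000004.1	HspS-PCC7336	synechococcus_host	1
Synechococcus sp. RS9917	ZP_01079326.1	HspS-RS9917	synechococcus_host	1
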