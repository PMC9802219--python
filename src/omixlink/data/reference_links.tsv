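spectrum_id	true_gcf	pred_gcf_1	pred_gcf_2	pred_gcf_3	annotation
CCMSLIB00004679298	GCF450	GCF360	GCF450	GCF360	Orfamide A
CCMSLIB00004679299	GCF450	GCF360	GCF450	GCF360	Orfamide B
CCMSLIB00004679300	GCF450	GCF360	GCF450	GCF360	Orfamide C
CCMSLIB00000001573	GCF468	GCF468	GCF468	GCF235	Barbamide
CCMSLIB00000001575	GCF468	GCF468	GCF468	GCF235	Barbamide
CCMSLIB00000001706	GCF471	GCF471	GCF498	GCF550	Jamaicamide A
CCMSLIB00000001708	GCF471	GCF471	GCF498	GCF550	Jamaicamide C
CCMSLIB00000579285	GCF476	GCF476	GCF219	GCF235	Albicidin
CCMSLIB00004681475	GCF476	GCF476	GCF219	GCF235	Propionyl-albicidin
CCMSLIB00004681481	GCF476	GCF476	GCF219	GCF235	Beta-methoxy-albicidin
CCMSLIB00004681486	GCF476	GCF476	GCF219	GCF235	Carbamoyl-beta-methoxy-albicidin
CCMSLIB00004681487	GCF476	GCF476	GCF219	GCF235	Carbamoyl-beta-methoxy-asn-albicidin
CCMSLIB00000840594	GCF488	GCF740	GCF740	GCF739	Nevaltophin D
CCMSLIB00005724004	GCF498	GCF471	GCF498	GCF550	Cryptomaldamide
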