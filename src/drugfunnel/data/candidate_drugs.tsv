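drug	original_indication	score	target	evidence_level	evidence_ids
Clomifene	Ovulation inducer	97.84	ESR1	-	PMID:25624908
Tamoxifen	Treat estrogen receptor-positive metastatic breast cancer	96.86	ESR1	Phase 2	PMID:12174927;PMID:9641456
Fulvestrant	Metastatic breast cancer	96.06	ESR1	-	-
Raloxifene	Prevention and treatment of osteoporosis in postmenopausal women	96.04	ESR1	-	PMID:32940862
Sunitinib	Treatment of advanced renal cell carcinoma	89.59	PDGFRB	Phase 2	NCT02713763
Midostaurin	Treatment in adult patients with high-risk acute myeloid leukemia (AML)	89.03	PRKCA	-	-
Bosutinib	Treatment of chronic, accelerated, or blast-phase Philadelphia chromosome-positive (Ph+) chronic myelogenous leukemia (CML)	88.17	BCR	Phase 1	NCT01025570
Everolimus	Treatment of postmenopausal women with advanced hormone receptor-positive	87.7	MTOR	Phase 2	NCT00560963
Afatinib	Advanced or metastatic non-small-cell lung cancer (NSCLC)	86.93	EGFR	Phase 2	NCT01728818
Palbociclib	Advanced/metastatic breast cancer	84.85	CDK4	Phase 2	NCT02806648
Vorinostat	Treatment of cutaneous manifestations in patients with cutaneous T-cell lymphoma	83.12	HDAC1	Phase 1	NCT00983268
Toremifene	Treatment of metastatic breast cancer	80.82	ESR1	-	-
Axitinib	Kidney cell cancer and investigated for use/treatment in pancreatic and thyroid cancer	80.4	FLT1	Phase 3	NCT00471146
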