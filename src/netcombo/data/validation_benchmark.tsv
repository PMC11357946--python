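cancer_type	drug_a	drug_b	s_ab	overlap	prediction	ground_truth
Pancreatic cancer	Sorafenib	Dihydroartemisinin	-0.142	1	True	True
Non-small cell lung cancer	Triptolide	Curcumin	0.230	0	False	False
Non-small cell lung cancer	Gemcitabine	Triptolide	0.205	0	False	False
Non-small cell lung cancer	Gemcitabine	Tanshinone IIA	0.716	0	False	False
Non-small cell lung cancer	Osimertinib	Tanshinone IIA	0.743	0	False	False
Non-small cell lung cancer	Metformin	Gemcitabine	-0.077	0	False	False
Non-small cell lung cancer	Metformin	Tanshinone IIA	0.713	1	False	False
Non-small cell lung cancer	Gemcitabine	Osimertinib	0.042	1	False	False
Non-small cell lung cancer	Dihydroartemisinin	Metformin	0.063	0	False	False
Breast cancer	Bortezomib	Curcumin	-0.071	0	False	False
Breast cancer	Curcumin	Gemcitabine	-0.202	1	True	False
Breast cancer	Bortezomib	Dihydroartemisinin	-0.334	1	True	False
Breast cancer	Gemcitabine	Palbociclib	0.281	1	False	False
Breast cancer	Palbociclib	Curcumin	0.287	0	False	True
Breast cancer	Curcumin	Sorafenib	-0.376	1	True	False
Colorectal cancer	Curcumin	Bortezomib	-0.071	1	True	True
Acute myeloid leukemia	Bortezomib	Dihydroartemisinin	-0.334	2	True	True
Acute myeloid leukemia	Decitabine	Palbociclib	0.598	0	False	False
Acute myeloid leukemia	Bortezomib	Palbociclib	0.164	1	False	False
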