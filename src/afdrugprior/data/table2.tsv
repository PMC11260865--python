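drug_name	target_symbols	max_level	overall_effect	comparator	black_box	withdrawn	high_priority
Amiodarone	KCNH2	GUIDELINE	EXISTING_TREATMENT		Pulmonary Toxicity, Hepatotoxicity, Cardiotoxicity	false	false
Atenolol	ADRB1	GUIDELINE	EXISTING_TREATMENT		Cardiotoxicity	false	false
Bepridil	CACNA1G	GUIDELINE	EXISTING_TREATMENT			false	false
Bisoprolol	ADRB1	GUIDELINE	EXISTING_TREATMENT			false	false
Carvedilol	ADRA1A;ADRB1	GUIDELINE	EXISTING_TREATMENT			false	false
Disopyramide	SCN10A;SCN5A	GUIDELINE	EXISTING_TREATMENT		Cardiotoxicity	false	true
Dofetilide	KCNH2	GUIDELINE	EXISTING_TREATMENT		Cardiotoxicity	false	false
Dronedarone	HCN4;KCNJ2;SCN10A;SCN5A	GUIDELINE	EXISTING_TREATMENT		Mortaility Risk	false	true
Esmolol	ADRB1	GUIDELINE	EXISTING_TREATMENT			false	false
Flecainide	SCN5A	GUIDELINE	EXISTING_TREATMENT		Cardiotoxicity	false	true
Ibutilide	KCNH2	GUIDELINE	EXISTING_TREATMENT		Cardiotoxicity	false	false
Landiolol	ADRB1	GUIDELINE	EXISTING_TREATMENT			false	false
Metoprolol	ADRB1	GUIDELINE	EXISTING_TREATMENT			false	false
Nadolol	ADRB1	GUIDELINE	EXISTING_TREATMENT		Cardiotoxicity	false	false
Nebivolol	ADRB1	GUIDELINE	EXISTING_TREATMENT			false	false
Procainamide	SCN10A;SCN5A	GUIDELINE	EXISTING_TREATMENT		Musculoskeletatl Toxicity, Haematological Toxicity, Cardiotoxicity	false	true
Propafenone	ADRB1;SCN10A;SCN5A	GUIDELINE	EXISTING_TREATMENT		Mortaility Risk	false	true
Propranolol	ADRB1	GUIDELINE	EXISTING_TREATMENT		Cardiotoxicity	false	false
Quinidine	SCN10A;SCN5A	GUIDELINE	EXISTING_TREATMENT		Cardiotoxicity	false	true
Sotalol	ADRB1;KCNH2	GUIDELINE	EXISTING_TREATMENT		Cardiotoxicity	false	true
Vernakalant	KCND3;KCNH2;KCNJ5;SCN5A	GUIDELINE	EXISTING_TREATMENT			false	true
Colchicine	TUBB3	SYSTEMATIC_REVIEW	BENEFICIAL			false	false
Methylprednisolone	NR3C1	SYSTEMATIC_REVIEW	BENEFICIAL			false	true
Acebutolol	ADRB1	SYSTEMATIC_REVIEW	BENEFICIAL			false	false
Dexamethasone	NR3C1	SYSTEMATIC_REVIEW	BENEFICIAL			false	true
Hydrocortisone	NR3C1	SYSTEMATIC_REVIEW	NEUTRAL			false	true
Ivabradine	HCN4	SYSTEMATIC_REVIEW	HARMFUL			false	true
Liothyronine	THRB	SYSTEMATIC_REVIEW	NEUTRAL		Against use in weight loss	false	true
Mavacamtam	MYH6;MYH7;MYL4	SYSTEMATIC_REVIEW	NEUTRAL			false	true
Roflumilast	PDE4B	SYSTEMATIC_REVIEW	BENEFICIAL			false	true
Timolol	ADRB1	SYSTEMATIC_REVIEW	BENEFICIAL			false	false
Prednisolone	NR3C1	RCT	NEUTRAL			false	false
AZD1305	KCNH2;SCN5A	RCT	BENEFICIAL			false	true
AZD7009	KCNH2;SCN5A	RCT	BENEFICIAL			false	true
Beclomethasone Dipropionate	NR3C1	RCT	BENEFICIAL			false	true
Betaxolol	ADRB1	RCT	NEUTRAL	other drug in same class		false	false
Bucindolol	ADRA1A;ADRB1	RCT	BENEFICIAL	other drug in same class		false	false
Carperitide	NPR3	RCT	BENEFICIAL			false	true
Cilostazol	PDE3A	RCT	HARMFUL		Contraindicated In Heart Failure	false	false
Conjugated Estrogens	ESR2	RCT	NEUTRAL		Endometrial cancer risk, Cariovascular risk, Dementia risk	false	true
Dobutamine	ADRB1	RCT	NEUTRAL	other drug in same class		false	false
Doxazosin	ADRA1A	RCT	HARMFUL			false	false
Duloxetine	SLC6A4	RCT	NEUTRAL		Psychiatric Toxicity	false	false
Erlosamide	SCN10A;SCN5A	RCT	NEUTRAL			false	true
Isoproterenol	ADRB1	RCT	NEUTRAL	other drug in same class		false	false
Levosimendan	PDE3A;TNNI3	RCT	MIXED			false	false
Lidocaine	SCN10A;SCN5A	RCT	BENEFICIAL		For strict dosing under the age of 3 otherwise mortaility risk	false	true
Meprednisone	NR3C1	RCT	NEUTRAL			false	true
Milrinone	PDE3A	RCT	BENEFICIAL			false	false
Nomifensine	SLC6A4	RCT	NEUTRAL			true	false
Omecamtiv Mecarbil	MYH6;MYH7;MYL4	RCT	NEUTRAL			false	true
Prednisone	NR3C1	RCT	NEUTRAL			false	true
Ranolazine	SCN5A	RCT	BENEFICIAL			false	true
Tedisamil	KCND3;KCNH2	RCT	BENEFICIAL			false	true
Theophylline	PDE3A;PDE4B	RCT	NEUTRAL			false	true
Tosedostat	AOPEP;ENPEP	RCT	HARMFUL			false	true
Vinorelbine	TUBB3	RCT	HARMFUL		Haematological Toxicity, Infectious Disease	false	false
Bortezomib	PSMB7;PSMD3	OBSERVATIONAL	POTENTIAL_HARM			false	true
Abiraterone	SRD5A3	OBSERVATIONAL	POTENTIAL_HARM			false	false
Carfilzomib	PSMB7;PSMD3	OBSERVATIONAL	POTENTIAL_HARM			false	true
Cocaine	SCN10A;SCN5A	OBSERVATIONAL	POTENTIAL_HARM		Misuse	false	true
Docetaxel	TUBB3	OBSERVATIONAL	POTENTIAL_HARM		Gastrointestinal Toxicity, Haematological Toxicity, Respiratory Toxicity, Dermatological Toxicity, Vascular Toxicity, Immune System Toxicity, Hepatotoxicity	false	false
Elotuzumab	SLAMF7	OBSERVATIONAL	POTENTIAL_HARM			false	false
Ixazomib	PSMB7;PSMD3	OBSERVATIONAL	POTENTIAL_HARM			false	true
Levothyroxine	THRB	OBSERVATIONAL	POTENTIAL_HARM		Against use in weight loss	false	true
Metformin	NDUFAF3;NDUFB10	OBSERVATIONAL	MIXED			false	true
Methamphetamine	SLC6A4	OBSERVATIONAL	POTENTIAL_HARM			true	false
Midostaurin	PRKCA	OBSERVATIONAL	POTENTIAL_HARM			false	true
Raloxifene	ESR2	OBSERVATIONAL	NEUTRAL		Respiratory Toxicity, Vascular Toxicity, Neurotoxicity	false	true
Regorafenib	FGFR1;FGFR2;RAF1	OBSERVATIONAL	POTENTIAL_HARM		Hepatotoxicity	false	false
Sorafenib	RAF1	OBSERVATIONAL	POTENTIAL_HARM			false	false
Trastuzumab	ERBB2	OBSERVATIONAL	NEUTRAL		Teratogenicity, Cardiotoxicity, Respiratory Toxicity	false	true
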