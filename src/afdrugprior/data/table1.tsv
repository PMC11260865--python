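hgnc_symbol	approved_name	location	target_class	twas_tissues	eqtl_tissues
ACVR2B	activin A receptor type 2B	Cell membrane	Enzyme
ADRA1A	adrenoceptor alpha 1A	Nucleus membrane, Cell membrane, Membrane	Membrane receptor
ADRB1	adrenoceptor beta 1	Cell membrane, Early endosome	Membrane receptor
AOPEP	aminopeptidase O (putative)	Nucleus, [Isoform 3]: Cytoplasm	Enzyme	RA	RA;LV
BLK	BLK proto-oncogene, Src family tyrosine kinase	Cell membrane	Enzyme
CA4	carbonic anhydrase 4	Cell membrane	Enzyme
CACNA1G	calcium voltage-gated channel subunit alpha1 G	Cell membrane, Cytoplasm	Ion channel
CDC7	cell division cycle 7	Nucleus	Enzyme, Other cytosolic protein		LV
CHRM2	cholinergic receptor muscarinic 2	Cell membrane, Postsynaptic cell membrane	Membrane receptor	LV	LV
ENPEP	glutamyl aminopeptidase	Cell membrane	Enzyme
EPAS1	endothelial PAS domain protein 1	Nucleus, Nucleus speckle	Transcription factor
EPHA3	EPH receptor A3	[Isoform 1]: Cell membrane, [Isoform 2]: Secreted	Enzyme
ERBB2	erb-b2 receptor tyrosine kinase 2	Cell membrane, Cell projection, [Isoform 1]: Cell membrane, Early endosome, Cytoplasm, Nucleus, [Isoform 2]: Cytoplasm, [Isoform 3]: Cytoplasm	Enzyme	RA;LV
ERBB4	erb-b2 receptor tyrosine kinase 4	Cell membrane, [ERBB4 intracellular domain]: Nucleus, Mitochondrion	Enzyme
ESR2	estrogen receptor 2	Nucleus	Transcription factor	RA
FDFT1	farnesyl-diphosphate farnesyltransferase 1	Endoplasmic reticulum membrane	Enzyme	LV
FGFR1	fibroblast growth factor receptor 1	Cell membrane, Nucleus, Cytoplasm, Cytoplasmic vesicle	Enzyme
FGFR2	fibroblast growth factor receptor 2	Cell membrane, Golgi apparatus, Cytoplasmic vesicle, [Isoform 1]: Cell membrane, [Isoform 3]: Cell membrane, [Isoform 8]: Secreted, [Isoform 13]: Secreted	Enzyme, Secreted protein
HBEGF	heparin binding EGF like growth factor	[Heparin-binding EGF-like growth factor]: Secreted, [Proheparin-binding EGF-like growth factor]: Cell membrane	Secreted protein
HCN4	hyperpolarization activated cyclic nucleotide gated potassium channel 4	Cell membrane	Ion channel
IGF1R	insulin like growth factor 1 receptor	Cell membrane	Enzyme	LV	LV
IL6R	interleukin 6 receptor	[Isoform 1]: Cell membrane, [Isoform 2]: Secreted, [Soluble interleukin-6 receptor subunit alpha]: Secreted	Membrane receptor, Secreted protein	RA
IMPDH1	inosine monophosphate dehydrogenase 1	Cytoplasm, Nucleus	Enzyme
ITGA2B	integrin subunit alpha 2b	Membrane	Membrane receptor
ITGB1	integrin subunit beta 1	Cell membrane, Cell projection, Melanosome, Cleavage furrow, Cell junction, Cell surface, [Isoform 5]: Cell membrane	Membrane receptor	RA
KCND3	potassium voltage-gated channel subfamily D member 3	Cell membrane, Cell projection	Ion channel	RA;LV
KCNH2	potassium voltage-gated channel subfamily H member 2	Cell membrane	Ion channel, Membrane receptor
KCNJ2	potassium inwardly rectifying channel subfamily J member 2	Membrane	Ion channel
KCNJ5	potassium inwardly rectifying channel subfamily J member 5	Membrane	Ion channel	RA;LV	RA;LA;LV
LAMB2	laminin subunit beta 2	Secreted	Structural protein
MAPT	microtubule associated protein tau	Cytoplasm, Cell membrane, Cell projection	Other cytosolic protein	RA;LV	RA;LV
MC4R	melanocortin 4 receptor	Cell membrane	Membrane receptor
MET	MET proto-oncogene, receptor tyrosine kinase	Membrane, [Isoform 3]: Secreted	Enzyme
MTNR1A	melatonin receptor 1A	Cell membrane	Membrane receptor
MYH6	myosin heavy chain 6	Cytoplasm	Unclassified protein
MYH7	myosin heavy chain 7	Cytoplasm	Unclassified protein
MYL4	myosin light chain 4	Cell membrane	Unclassified protein
NDUFAF3	NADH:ubiquinone oxidoreductase complex assembly factor 3	Nucleus, Mitochondrion inner membrane	Enzyme		RA
NDUFB10	NADH:ubiquinone oxidoreductase subunit B10	Mitochondrion inner membrane	Enzyme	RA;LV
NPR3	natriuretic peptide receptor 3	Cell membrane	Membrane receptor, Enzyme		RA
NR3C1	nuclear receptor subfamily 3 group C member 1	[Isoform Alpha]: Cytoplasm, Nucleus, Mitochondrion, Cytoplasm, [Isoform Beta]: Nucleus, [Isoform Alpha-B]: Nucleus	Transcription factor	LV
PDE3A	phosphodiesterase 3A	Membrane, Cytoplasm	Enzyme
PDE4B	phosphodiesterase 4B	[Isoform PDE4B5]: Cytoplasm, Cell membrane	Enzyme
POLR2A	RNA polymerase II subunit A	Nucleus, Cytoplasm, Chromosome	Enzyme
PRKCA	protein kinase C alpha	Cytoplasm, Cell membrane, Mitochondrion membrane	Enzyme		RA;LV
PSMB7	proteasome 20S subunit beta 7	Cytoplasm, Nucleus	Enzyme, Unclassified protein	RA;LV
PSMD3	proteasome 26S subunit, non-ATPase 3	Nuceloplasm	Enzyme	LV
PTK2	protein tyrosine kinase 2	Cell junction, Cell membrane, Cytoplasm, Nucleus	Enzyme
RAF1	Raf-1 proto-oncogene, serine/threonine kinase	Cytoplasm, Cell membrane, Mitochondrion, Nucleus	Enzyme
RPL32	ribosomal protein L32	Cytoplasm	Unclassified protein
RPS2	ribosomal protein S2	Cytoplasm, Nucleus	Unclassified protein
RPSA	ribosomal protein SA	Cell membrane, Cytoplasm, Nucleus	Unclassified protein	LV	RA
SCN10A	sodium voltage-gated channel alpha subunit 10	Cell membrane	Ion channel	RA;LV	LA
SCN5A	sodium voltage-gated channel alpha subunit 5	Cell membrane, Cytoplasm	Auxiliary transport protein, Ion channel	RA	LA
SIRT1	sirtuin 1	Nucleus, Cytoplasm, [SirtT1 75 kDa fragment]: Cytoplasm, Mitochondrion	Epigenetic regulator	RA;LV
SLAMF7	SLAM family member 7	Membrane	Membrane receptor
SLC6A4	solute carrier family 6 member 4	Cell membrane, Endomembrane system, Synapse, Cell junction	Transporter
SMAD7	SMAD family member 7	Nucleus, Cytoplasm	Unclassified protein
SRD5A3	steroid 5 alpha-reductase 3	Endoplasmic reticulum membrane	Enzyme
SYK	spleen associated tyrosine kinase	Cell membrane, Cytoplasm	Enzyme
THRB	thyroid hormone receptor beta	Nucleus	Transcription factor	RA;LV	RA;LV
TNFSF12	TNF superfamily member 12	Cell membrane, [Tumor necrosis factor ligand superfamily member 12, secreted form]: Secreted, [Isoform TWE-PRIL]: Cell membrane	Secreted protein
TNFSF13	TNF superfamily member 13	Secreted	Secreted protein
TNNI3	troponin I3, cardiac type	Cytoplasm	Unclassified protein
TNNT3	troponin T3, fast skeletal type	Sarcoplasmic Reticulum	Unclassified protein	LV
TUBB3	tubulin beta 3 class III	Cytoplasm, Cell projection	Structural protein
WT1	WT1 transcription factor	Nucleus, Cytoplasm, [Isoform 1]: Nucleus speckle, [Isoform 4]: Nucleus	Unclassified protein
XPO1	exportin 1	Cytoplasm, Nucleus	Unclassified protein
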