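module	sycon_gene	amphimedon_gene	description
AmqTCONS_00003141	scigt010895	Aqu2.1.43387_001	mitochondrial dicarboxylate carrier
AmqTCONS_00003141	scigt017797	Aqu2.1.41074_001	protein disulfide-isomerase a5-like
AmqTCONS_00003141	scigt001771	Aqu2.1.30885_001	sh3 and px domain-containing protein 2a-like
AmqTCONS_00003141	scigt016036	Aqu2.1.36626_001	adp-ribosylation factor gtpase-activating protein 2-like
AmqTCONS_00003141	scigt018255	Aqu2.1.30885_001	sh3 and px domain-containing protein 2a-like
AmqTCONS_00003141	scigt000612	Aqu2.1.41568_001	tgf-beta receptor type-1
AmqTCONS_00003141	scigt008994	Aqu2.1.41568_001	tgf-beta receptor type-1
AmqTCONS_00001337-9	scigt017951	Aqu2.1.43947_001	arylsulfatase b-like
AmqTCONS_00001337-9	scigt017951	Aqu2.1.24502_001	arylsulfatase b-like
AmqTCONS_00001337-9	scigt017951	Aqu2.1.39727_001	arylsulfatase
AmqTCONS_00001337-9	scigt017951	Aqu2.1.41029_001	arylsulfatase
AmqTCONS_00001337-9	scigt017951	Aqu2.1.37909_001	sulfatase
AmqTCONS_00001337-9	scigt014545	Aqu2.1.37909_001	sulfatase
AmqTCONS_00001337-9	scigt014545	Aqu2.1.41029_001	arylsulfatase
AmqTCONS_00001337-9	scigt014545	Aqu2.1.39727_001	arylsulfatase
AmqTCONS_00001337-9	scigt017997	Aqu2.1.32274_001	usherin
AmqTCONS_00001337-9	scigt020120	Aqu2.1.28087_001	lysosomal alpha-glucosidase-like isoform x2
AmqTCONS_00001337-9	scigt020423	Aqu2.1.35119_001	filamin-c-like isoform x3
AmqTCONS_00001337-9	scigt000557	Aqu2.1.32241_001	myosin-i heavy chain
AmqTCONS_00001337-9	scigt008273	Aqu2.1.36394_001	deleted in malignant brain tumors 1
AmqTCONS_00001337-9	scigt017951	Aqu2.1.42755_001	arylsulfatase b-like
AmqTCONS_00003502	scigt000138	Aqu2.1.44676_001	actin family protein
AmqTCONS_00003502	scigt001771	Aqu2.1.38758_001	tyrosine-protein kinase lck
AmqTCONS_00003502	scigt005362	Aqu2.1.44676_001	actin family protein
AmqTCONS_00003502	scigt004922	Aqu2.1.40987_001	unconventional myosin-viia
AmqTCONS_00003502	scigt008792	Aqu2.1.24982_001	adenylyl cyclase-associated protein 1
AmqTCONS_00003502	scigt012572	Aqu2.1.40987_001	unconventional myosin-viia
AmqTCONS_00003502	scigt014349	Aqu2.1.32914_001	pleckstrin homology domain-containing family g member 1-like
AmqTCONS_00003502	scigt016045	Aqu2.1.28519_001	ap-2 complex subunit alpha-1-like
AmqTCONS_00003502	scigt020995	Aqu2.1.43989_001	protein plant cadmium resistance 3-like
AmqTCONS_00003502	scigt021992	Aqu2.1.44676_001	actin family protein
AmqTCONS_00003502	scigt022018	Aqu2.1.44676_001	actin family protein
AmqTCONS_00003502	scigt025009	Aqu2.1.40987_001	unconventional myosin-viia
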