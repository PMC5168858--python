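# Signature IDs used for GPCR class assignment and N-terminal architecture
# flags.  kind is "class" or "flag"; match_on is "interpro" (match the
# InterPro accession of a domain hit) or "signature" (match the member-db
# accession, e.g. a SCOP superfamily id).
#id	kind	label	match_on	note
IPR017978	class	class_c	interpro	GPCR class C (glutamate/metabotropic) 7TM domain
IPR017452	class	rhodopsin_dicty_car	interpro	GPCR rhodopsin-like 7TM
IPR017981	class	rhodopsin_dicty_car	interpro	cAMP receptor (Dicty-CAR) family
IPR001828	flag	anf	interpro	ANF receptor-type ligand-binding domain
IPR011050	flag	pectin_lyase	interpro	pectin lyase fold
IPR012334	flag	pectin_lyase	interpro	pectin lyase fold/virulence factor
IPR006626	flag	beta_helix	interpro	parallel beta-helix repeat
IPR000742	flag	egf_like	interpro	EGF-like domain
SSF53850	flag	sbp_type_ii	signature	periplasmic binding protein-like II (SBP Type II)
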