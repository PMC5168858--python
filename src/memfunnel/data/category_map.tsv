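# Default TC-prefix -> (functional category, substrate class, sugar family) map.
# Longest matching prefix wins.  Edit or replace via --category-map.
# NOTE: the SSS (solute sodium symporter) family is mapped at 2.A.2 following
# the source classification used by this pipeline's reference configuration;
# TCDB canonically lists 2.A.2 as the glycoside-pentoside-hexuronide family
# and SSS as 2.A.21 - override here if you prefer the canonical numbering.
#tc_prefix	category	substrate	sugar_family	note
3.A.5	protein_biogenesis_secretion	unassigned	none	general secretory pathway (Sec61/SRP)
1.A.33	protein_biogenesis_secretion	unassigned	none	heat shock protein channels
3.A.16	protein_biogenesis_secretion	unassigned	none	ER retrotranslocon
1.F.1	protein_biogenesis_secretion	unassigned	none	synaptosomal vesicle fusion pore (SNARE)
1.A.55	protein_biogenesis_secretion	unassigned	none	synaptic vesicle-associated Ca2+ channels
1.A.31	protein_biogenesis_secretion	unassigned	none	annexin-like proteins
1.B.33	organelle_import	unassigned	none	mitochondrial/plastid outer-membrane import (TOM-like)
1.B.8	organelle_import	unassigned	none	mitochondrial outer-membrane porin
3.A.8	organelle_import	unassigned	none	mitochondrial inner-membrane import (TIM)
3.A.9	organelle_import	unassigned	none	chloroplast envelope import
3.A.20	peroxisomal_import	unassigned	none	peroxisomal import machinery
1.I.1	nuclear_transport	unassigned	none	nuclear pore complex
3.A.18	nuclear_transport	unassigned	none	nuclear mRNA export
3.A.22	nuclear_transport	unassigned	none	nuclear export complexes
9.A.50	nuclear_transport	unassigned	none	RNA maturation/nuclear export factors
3.D.1	other	unassigned	none	energy conversion (NDH)
3.D.10	other	unassigned	none	energy conversion
4.C.1	other	unassigned	none	fatty acid translocators
8	other	unassigned	none	accessory factors
9	other	unassigned	none	incompletely characterised systems
2.A.1	solute_transport	sugars_metabolites	mfs	major facilitator superfamily sugar porters
2.A.2	solute_transport	sugars_metabolites	sss	solute sodium symporter family (see note above)
2.A.123	solute_transport	sugars_metabolites	sweet	SWEET sugar transporters
3.A.1	solute_transport	sugars_metabolites	abc_sbp	ABC uptake systems / substrate-binding proteins
2.A.1.19	solute_transport	sugars_metabolites	none	organic cation transporters
2.A.18	solute_transport	sugars_metabolites	none	amino acid/auxin permeases
2.A.22	solute_transport	sugars_metabolites	none	neurotransmitter:sodium symporters
2.A.79	solute_transport	sugars_metabolites	none	threonine/serine exporters
2.A.85	solute_transport	sugars_metabolites	none	aromatic acid exporters
1.A.11	solute_transport	sugars_metabolites	none	ammonia channels
2.A.50	solute_transport	sugars_metabolites	none	glycerol uptake (sugar alcohols)
1.A.16	solute_transport	sugars_metabolites	none	formate/nitrite channels
2.A.7.11	solute_transport	sugars_metabolites	none	nucleotide-sugar transporters
2.A.7.12	solute_transport	sugars_metabolites	none	nucleoside transporters
2.A.29	solute_transport	sugars_metabolites	none	mitochondrial carriers (ATP/ADP etc.)
2.A.1.2	solute_transport	drugs_lipids	none	drug:proton antiporters (DHA1)
2.A.1.3	solute_transport	drugs_lipids	none	drug:proton antiporters (DHA2)
2.A.66	solute_transport	drugs_lipids	none	multi antimicrobial extrusion (MATE)
3.A.1.201	solute_transport	drugs_lipids	none	ABC drug exporters (MDR)
3.A.1.211	solute_transport	drugs_lipids	none	ABCA lipid flippases
3.A.3.8	solute_transport	drugs_lipids	none	P-type ATPase lipid flippases
1.A.1	solute_transport	inorganic_ions_metals	none	voltage-gated cation channels
2.A.40	solute_transport	inorganic_ions_metals	none	chloride channels
3.A.2	solute_transport	inorganic_ions_metals	none	V-type ATPases
3.A.3	solute_transport	inorganic_ions_metals	none	P-type ATPases
2.A.59	solute_transport	inorganic_ions_metals	none	arsenite transporters
1.A.26	solute_transport	inorganic_ions_metals	none	magnesium transporters
2.A.5	solute_transport	inorganic_ions_metals	none	zinc/iron permeases
2.A.89	solute_transport	inorganic_ions_metals	none	vacuolar iron transporters
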