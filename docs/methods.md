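# Methods

This note records the model behind each pipeline stage, the parameters
that matter, what the synthetic data does and does not emulate, and the
choices made where the design was genuinely open.

## ORF extraction and the representative protein

ORFs are enumerated in all six frames.  An ORF is a closed ATG→in-frame
stop span (stop codon inside the nucleotide span, outside the protein), or
an open-ended span truncated by a transcript end: a 5′-partial run from
the frame start to the first stop (only when the first codon is not ATG,
so closed ORFs are not duplicated), and a 3′-partial run from an ATG with
no downstream stop.  Every internal ATG opens its own ORF.  Open-ended
ORFs are kept and flagged because de novo assembled transcripts are
frequently truncated.  Coordinates are 1-based inclusive on the forward
strand; the frame sign carries the strand (−k means frame +k of the
reverse complement).  Codons containing N translate to X even when the
ambiguity would resolve (e.g. ACN), keeping the output independent of the
ambiguity-resolution behaviour of any particular library.

The **representative protein** of a transcript is its longest ORF (ties:
frame order +1,+2,+3,−1,−2,−3, then 5′ coordinate).  No selection rule is
canonical for transcriptome data; longest-ORF is the conventional default
and is deterministic.  Every per-transcript table uses the representative
only, so a transcript is never double-counted.  The default minimum ORF
length is 50 codons (configurable); short spurious ORFs below that are
invisible to the pipeline.

Antisense calls use the annotation frame of the representative protein:
in a strand-specific assembly, a transcript whose annotated ORF lies in a
negative frame is the reverse complement of a coding mRNA and is treated
as non-coding.  A transcript with a negative-frame representative but no
annotation at all is *not* called antisense — without a hit there is no
evidence the negative-frame product is real — and falls through to the
topology funnel.

## Topology

Three predictor-output dialects are parsed (TMHMM short, SignalP short
tabular, Phobius short tabular).  Multi-predictor calls are combined by
**union** by default: TM segment sets are interval-unioned (adjacent or
overlapping spans merge), a signal peptide is present if any source says
so, and the cleavage site is the maximum over sources.  Union maximises
sensitivity, which matches the inclusive "signal peptide and/or TM
segment" definition of trafficked proteins; `intersection` and `priority`
modes exist for sensitivity analysis.  Proteins absent from all topology
files get no profile and are binned soluble with a `no_profile` flag so
the funnel stays a partition.

The count that drives classification is the **non-cleaved TM count**: a
predicted helix whose start lies at or before the SP cleavage site is the
signal peptide itself as seen by a hydrophobicity-based predictor, not a
membrane anchor, and is discounted.  This resolves the well-known SP/TM
ambiguity in one deterministic rule.

The fallback predictor computes Kyte–Doolittle mean hydropathy over a
19-residue sliding window; maximal runs of windows above 1.6 become TM
segments (union of the window spans).  A segment starting within the
first 30 residues is additionally reported as an SP candidate when a
small residue (A/G/S — the signal-peptidase −1/−3 preference) occurs at
the segment tail or within 8 residues downstream; the tail is searched
first because alanine-rich cleavage motifs score as hydrophobic and end
up inside the detected segment.  Window 19 and threshold 1.6 are standard
hydropathy-scan settings; both are arguments.  The fallback makes no
claim to TMHMM/Phobius accuracy: on real proteins it will over-merge
closely spaced helices and mistake N-terminal helices for SPs, and
β-barrels are invisible to it entirely (the TCDB route, which ignores
topology, is the intended path for those).

## The funnel

Per transcript: antisense ≻ topology.  k = non-cleaved TM count; k = 0
with SP → secreted, k = 0 without → soluble, k = 1 → bitopic membrane,
k ≥ 2 → polytopic membrane.  Classes partition each strain exactly, and
the funnel report gives total → trafficked (secreted + membrane) →
membrane, with bitopic broken out because single-pass proteins may be
shed.  Antisense transcripts are excluded from the trafficked numerator
but kept in the total denominator.

## GO roles

Keyword matching on GO term *names* (case-insensitive substring), not
GO-graph reasoning, in strict precedence: Transport ("transport",
"symport", "v-type atpase") ≻ Sensing and Signaling ("receptor",
"signal", "sensor") ≻ Catalysis (final whitespace-delimited word ends in
"ase") ≻ Other ≻ Unknown (no GO terms).  The "-ase" suffix test is
deliberately blunt — it fires on final words like "base" — and is
restricted to the final word to keep the false positives bounded; this
imprecision is accepted and documented rather than patched, because the
rule's value is its transparency.  Five bins are reported (Unknown
distinct from Other).  Roles are computed for membrane-class proteins
only; percentages are of each strain's membrane set.

## TCDB transporter classification

Reciprocal coverage first: a hit survives iff the aligned span covers at
least 70 % of the query *and* at least 70 % of the subject (alignment
span over sequence length; boundary inclusive).  Then the smallest
E-value among survivors wins, with the inclusive cutoff E ≤ 10⁻³; ties
break by larger bit score, then lexicographic subject id, so the result
is permutation-invariant.  Both readings of the E-gate ("≤" vs "<")
appear in the literature describing this procedure; the inclusive form is
used everywhere here.

TC tags parse from the subject id or description; family- and
subfamily-level tags yield partial TcIds.  Binning is longest-prefix-wins
over an editable TSV map whose default rows cover the TC numbers of the
reference configuration: the secretory pathway and chaperone/vesicle
systems under protein biogenesis; TOM/TIM and outer-membrane porins under
organelle import (one merged bin for mitochondrial/plastid/hydrogenosomal
import); the nuclear pore and RNA export; peroxisomal import; energy
conversion, fatty-acid translocators and TCDB classes 8/9 under "other";
and the solute transporters split into sugars/metabolites, drugs/lipids
and inorganic ions/metals, with MFS (2.A.1), SSS (2.A.2), SWEET (2.A.123)
and ABC/SBP (3.A.1) as sugar-uptake families.  Longest-prefix ordering is
what lets DHA drug antiporters (2.A.1.2, 2.A.1.3) and ABC drug exporters/
flippases (3.A.1.201, 3.A.1.211, 3.A.3.8) override their sugar-family
parents.  The map records 2.A.2 as SSS following the reference
configuration even though TCDB canonically assigns that number to a
different family; the map is config, so users can override it.  Unmapped
prefixes fall into other/unassigned rather than erroring.

## GPCR discovery

Entry filter: a "gpcr" or "g-protein coupled receptor" keyword in any
annotation description AND a raw TM count of 7–9.  The raw
(pre-SP-discount) count is intentional: the upper bound exists precisely
to tolerate hydrophobic signal sequences that TM predictors also call as
helices, so discounting them first would defeat the gate.  The
heptahelical bundle is anchored at the C-terminus (the 7 most C-terminal
helices) because class C receptors carry their bundle there; with 8–9
predicted helices the extra N-terminal ones are treated as SP/artefact
helices preceding the bundle.  The extracellular N-terminal region is
residues 1 to bundle-start − 1, and a domain counts toward the
architecture only when wholly inside it (end strictly before the bundle) —
boundary-spanning hits are excluded for determinism.  Receptor class comes
from signatures anywhere in the protein (IPR017978 → class C; IPR017452/
IPR017981 → rhodopsin/Dicty-CAR); a protein carrying both is reported as
class C with an explicit conflict flag, never silently.  Architecture
flags: IPR001828 → ANF, IPR011050/IPR012334 → pectin lyase fold,
IPR006626 → parallel β-helix, IPR000742 → EGF-like, SCOP superfamily
SSF53850 (matched on the member-database accession, since it has no
InterPro integration) → SBP Type II.  The signature table is an editable
TSV.

## Synthetic data

The generator plants, per transcript, a localisation class, a GO role, an
optional TC tag with its category/substrate/family, and an optional GPCR
class with N-terminal architecture, then constructs a protein whose
sequence actually carries the implied features: hydrophobic 18–25-residue
stretches (L/I/V/F/A-rich) for each TM, an N-terminal hydrophobic core
with an A-X-A motif for signal peptides, long hydrophilic N-terminal
regions (250–500 residues) ahead of seven C-terminal helices for class C
GPCRs.  The protein is reverse-translated with random synonymous codons
and framed by TTAA-repeat flanks (stop codons in all six frames; TTAA is
its own reverse complement).  Because a purely hydrophilic codon stream
happens to contain no stop codons in one shifted frame, rare V/L residues
are sprinkled into hydrophilic stretches and their codons biased toward
GTA/TTA/CTA (and serine toward TCA), planting out-of-frame and
reverse-strand stops; the generator then verifies by re-extraction that
the planted ORF is the representative and re-samples codons in the rare
failure case.  Antisense transcripts are emitted reverse-complemented.

Default composition (per strain, configurable): 73 % soluble, 5 %
antisense, 6.8 % secreted, 6.5 % bitopic, 3.2 % polytopic, 4.5 % spread
over eleven transporter classes (one per category, four sugar families,
the ABC/SBP class planted as a secreted soluble protein), 1 % over four
GPCR architectures, with ~30 % of class C GPCRs carrying a signal
peptide.  This yields ≈ 22 % trafficked transcripts, about a third of
them secreted and almost half of the membrane set bitopic — the regime
reported for these fungal transcriptomes — while keeping every planted
class populated at n = 1000.  Class labels are drawn i.i.d. per
transcript, so planted fractions fluctuate binomially.

The emitted annotation bundle is exactly consistent with the truth at
noise 0: topology files in all three dialects (their union equals the
planted topology), a 14-column BLAST tabular whose subject ids embed the
planted TC tags with spans passing the reciprocal-coverage filter, decoy
hits with smaller E-values that fail coverage (exercising
filter-before-rank), spurious hits on non-transporters that fail coverage
or the E-gate, and an InterProScan-style TSV carrying the planted
signatures, descriptions and GO terms.  Noise corrupts each emitted
record independently with probability p by changing exactly one field —
±1 TM segment, a flipped SP call, an E-value pushed across the 10⁻³
boundary, a query span shrunk below 70 % coverage, or a domain record
blanked to "hypothetical protein" — never by deleting records, so file
parseability and classification robustness stay separable, and every
corruption actually changes the checked field (chance agreement is zero
at p = 1).

What passing tests on this data do **not** show: performance under
realistic codon usage or the extreme AT-richness of these genomes,
assembly fragmentation beyond simple ORF truncation, predictor-specific
error modes (the mock files are ideal-predictor outputs), or TCDB
database drift.  The round-trip results certify the bookkeeping and the
decision rules, not the upstream predictors.

## Numerical and degenerate-input choices

All text matching is case-insensitive; subject descriptions are preserved
verbatim because TC tags parse from them.  Descending alignment spans are
normalised ascending with an orientation flag.  E-value gates are
inclusive everywhere.  Zero-length strains produce empty tables rather
than errors; `max_evalue = 0` yields zero TCDB assignments but a complete
run.  Reports are byte-deterministic for a given config and input paths;
the manifest records thresholds and input SHA-256 checksums so a run can
be replayed.  Problem sizes in the shipped analyses (1000 transcripts per
strain for the reference study, 500 for the noise sweep with three seeds)
keep every planted class populated while the full suite and acceptance
script run in well under a minute each.

## Known limitations

Splice-aware gene prediction, coding-potential scoring, GO-slim mapping,
inside/outside loop orientation, β-barrel detection and phylogenetic
placement of receptors are out of scope.  The funnel trusts the topology
inputs; garbage predictions yield garbage classes.  Multi-ORF transcripts
contribute only their representative protein, so a transcript encoding
two transporter components is counted once.
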