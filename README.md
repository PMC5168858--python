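# memfunnel

Membrane-proteome mining of strand-specific transcriptomes, built for the
kind of dataset produced by de novo RNA-seq of non-model organisms — the
motivating case being anaerobic gut fungi (Neocallimastigomycota), whose
membrane transporters and receptors are of interest for biomass-conversion
engineering but whose genomes are poorly assembled.  Starting from
assembled transcripts plus standard annotation outputs (TMHMM/SignalP/
Phobius topology predictions, BLAST-tabular alignments against the
Transporter Classification Database, InterProScan domain/GO annotations),
the pipeline answers four questions per transcript:

1. **Where does the protein go?**  All ORFs are extracted in six frames;
   the longest is the representative protein.  Transcripts whose annotation
   lies in a negative reading frame (−1, −2, −3) of a strand-specific
   assembly are non-coding antisense.  The rest are funnelled by topology:
   with k = the number of transmembrane (TM) segments that are *not* the
   cleaved signal peptide (SP),

   | SP | k | class |
   |----|---|-------|
   | yes | 0 | secreted |
   | no | 0 | soluble |
   | — | 1 | bitopic membrane |
   | — | ≥2 | polytopic membrane |

2. **What does it do?**  Membrane proteins are binned by GO-term keywords
   in strict precedence: Transport ("transport", "symport", "V-type
   ATPase") ≻ Sensing and Signaling ("receptor", "signal", "sensor") ≻
   Catalysis (final word ends in "-ase") ≻ Other (annotated, no match) ≻
   Unknown (no GO terms).  A multifunctional protein is counted once, under
   its highest-precedence role.

3. **Is it a transporter component?**  Alignment hits against TCDB are kept
   only when the aligned span covers ≥ 70 % of *both* query and subject
   (reciprocal coverage); among survivors the smallest E-value wins,
   subject to E ≤ 10⁻³ (inclusive).  The five-tier TC identity tag
   (class.subclass.family.subfamily.system) of the best hit is binned by a
   longest-prefix category map into functional categories (solute
   transport, protein biogenesis/secretion, nuclear transport, peroxisomal
   import, organelle import, other), substrate classes
   (sugars/metabolites, drugs/lipids, inorganic ions/metals) and sugar
   uptake families (MFS, SSS, SWEET, ABC/SBP).  Every transcript is
   eligible regardless of its funnel class — many transporter subunits are
   only peripherally membrane-associated, and β-barrels evade
   hydrophobicity-based TM prediction.

4. **Is it a GPCR?**  Candidates need a "GPCR"/"G-protein coupled
   receptor" keyword in an annotation *and* 7–9 predicted TM segments (the
   raw count, so a hydrophobic signal sequence mistaken for a helix does
   not exclude a receptor).  The heptahelical bundle is the 7 most
   C-terminal helices; domains wholly before it define the extracellular
   N-terminal architecture (ANF, pectin lyase fold, parallel β-helix,
   EGF-like, SBP Type II), and InterPro signatures assign the receptor
   class (class C / glutamate vs rhodopsin–Dicty-CAR).

Because real transcriptome assemblies of this kind are rarely
redistributable, the package ships a first-class synthetic-data generator
(`memfunnel.simulate`) that emits transcript FASTA and all four annotation
file dialects with a fully known planted classification per transcript,
plus a tunable per-record corruption ("noise") model.  Every pipeline stage
is tested against this planted truth and against independent brute-force
oracles.

There is also a built-in Kyte–Doolittle hydropathy fallback predictor
(window 19, mean > 1.6) so the funnel can run with no topology files at
all; it is a deliberately simple heuristic, not a re-implementation of the
HMM predictors.

## Worked example

```
$ memfunnel simulate -n 300 --seed 2026 -o scratch/demo
wrote 900 transcripts (3 strains) to scratch/demo
```

then run the full pipeline on those files (the same thing
`analysis/02_run_pipeline.py` does):

```
$ python analysis/01_simulate.py --n 300
$ python analysis/02_run_pipeline.py
report bundle -> results/pipeline
label recovery vs planted truth:
    localization: 1.0000
            role: 1.0000
        category: 1.0000
       substrate: 1.0000
    sugar_family: 1.0000
      gpcr_class: 1.0000
      gpcr_flags: 1.0000
            mean: 1.0000
funnel: 900 transcripts -> 185 trafficked (20.6%)
```

With noiseless annotations every planted label is recovered exactly — the
funnel classes, GO roles, TCDB categories and GPCR architectures in the
report bundle equal the planted tallies.  About 21 % of transcripts are
trafficked (signal peptide and/or TM segment) under the default simulated
composition, roughly a third of those fully secreted, mirroring the
proportions typical of these fungal transcriptomes.
`analysis/03_noise_sweep.py` then corrupts annotation records with
increasing probability and shows mean recovery degrading monotonically
(1.00 → 0.88 → 0.61 → 0.50 for noise 0/0.1/0.3/0.5 at n=500).

All thresholds (coverage 0.70, E ≤ 10⁻³, TM gate 7–9, minimum ORF 50
codons, union merging of predictors) are exposed as CLI flags and
`RunConfig` fields; the TC category map and GPCR signature table are
editable TSVs under `src/memfunnel/data/`.

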