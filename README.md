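# marinerscan

Discovery and characterization of **Mariner-like elements (MLEs)** — DNA
transposons of the *Tc1/mariner* superfamily, *Mariner*/DD34D family — in
genome assemblies. The package is aimed at people doing transposable-element
annotation in newly assembled (often fragmented, short-read) genomes:
it mines contigs for MLE copies by homology, resolves each copy's terminal
structure, decides whether its transposase could still be functional, and
places it in a subfamily.

## What it computes

An autonomous MLE is ~1.0–1.4 kb: a single ORF encoding a 282–350 aa
transposase, flanked by untranslated regions and terminal inverted repeats
(TIRs, 13–32 bp), inserted at a TA dinucleotide that is duplicated on both
flanks (the TA target-site duplication, TSD). The pipeline:

1. **Homology mining** — a k-mer-seeded, Smith–Waterman-extended local
   search of every contig against an MLE query panel (both strands), with
   iterative re-querying using extracted near-complete copies. Hits are kept
   when alignment identity > 0.60 **and** query coverage > 0.60; retained
   candidates must be ≥ 1000 bp. Genomes are also screened for the related
   DD-families (Tc1/DD34E, maT/DD37D, GT/DD39D, VS/DD41D) with loose
   presence floors (identity ≥ 0.30, coverage ≥ 0.15).
2. **Terminal structure** — exhaustive TIR-pair detection in 60 bp terminal
   windows (length 13–32 bp, ≤ 15 % mismatch between the two copies,
   objective: max matches−mismatches), TSD flags from the 2 nt flanks, and a
   completeness call: *complete* (both TIRs) vs *truncated_5p/3p/both*, with
   contig-edge truncation flagged.
3. **Transposase analysis** — six-frame ORF finding (ATG-initiated,
   stop-terminated), premature-stop counting, a frameshift surrogate
   (reference coverage requires two reading frames), and motif scans:
   the DD34D catalytic triad (third aspartate exactly 34 residues after the
   second; DD34E would mean Tc1), the WVPHEL and YSPDL peptides (≤ 2
   substitutions), a helix-turn-helix heuristic and a basic-residue NLS
   window. A copy is **potentially active** iff it is complete *and* its ORF
   is intact (no premature stop, no frameshift, 310–345 aa) *and* the triad
   is DD34D; an intact ORF inside a truncated copy is reported separately.
4. **Subfamily assignment** — the ≥ 80 % identity rule (whole sequence, or
   TIR vs the subfamily TIR consensus as a fallback) plus clade membership
   in a neighbor-joining tree (center-star MSA, K2P distances, rooted on a
   Tc1 outgroup, column-resampling bootstrap). Agreement of the two rules is
   recorded per element.

Because real host genomes for this problem are typically unpublished, the
package ships a first-class **synthetic benchmark generator**: it builds
subfamily consensus elements with the full anatomy above and plants mutated
copies (synonymous-only divergence for intact copies; explicit premature
stops, triad knockouts, frameshifts and truncations for decayed ones) in
random-background genomes, together with an exact truth table for recovery
scoring. The default configuration emulates a published seven-species
survey: 121 elements, four subfamilies (*Mauritiana*, *Drosophila*,
*Vertumana*, *Irritans*), five potentially active copies, two intact-ORF
truncated copies, 106 complete / 15 truncated.

## Worked example

```bash
python examples/full_pipeline.py
```

simulates two small genomes with eight planted copies and runs the full
pipeline:

```
species  n_MLEs  Mauritiana  Drosophila  Vertumana  Irritans  length_kb  active  inactive  TIR_bp  complete  truncated
genomeA  5       1           2           1          1         1.2-1.4    1       4         22-30   4         1
genomeB  3       1           1           1          0         1.2-1.4    1       2         28-30   2         1

recall 1.00  precision 1.00  subfamily accuracy 1.00  activity accuracy 1.00
```

Each row mirrors the survey-table shape: total copies, per-subfamily
counts, length range, potentially-active/inactive split, TIR length range,
complete/truncated split. The recovery line compares the detected elements
1-to-1 against the planted truth (reciprocal interval overlap ≥ 0.9).

Other examples: `examples/simulate_benchmark.py` (the seven-genome default
benchmark and its truth), `examples/search_and_annotate.py` (per-element
structure annotation), `examples/motif_scan.py` (transposase motif report).

A CLI mirrors the library (`marinerscan simulate|search|annotate|classify|
report|score|run`), e.g.:

```bash
marinerscan simulate --seed 1 --outdir bench
marinerscan run --genome bench/S_chinensis.fasta --panel bench/panel.fasta \
    --truth bench/truth.tsv --outdir out
```

(The genome id is taken from the FASTA file stem, so keep the file names
`simulate` writes when scoring against its truth table.)

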