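# Methods

This note documents the models, heuristics and numerical choices behind
marinerscan, and what the synthetic benchmark does and does not show.

## Homology search

The mining step is a seed-and-extend local aligner, not a wrapper around an
external search tool. Contigs are indexed by exact k-mers (k = 12, ≥ 8
required); matches clustered on diagonals (band 16 nt, positional gap
≤ 400 nt, ≥ 2 seeds) define candidate windows that are aligned with an
affine-gap Smith–Waterman kernel (numba). Contigs ≤ 4 kb are aligned in
full (gated on a single shared k-mer), so on desk-size instances the
reported score equals the full-DP optimum — a property the tests verify
against an independent pure-Python DP oracle.

Scoring is match +1, mismatch −1, gap of length L costs 2 + (L−1). `N`
bases never match anything, so assembly gaps act as barriers. A raw score
floor (default 40) stands in for an E-value cutoff: E-value calibration is
database-size-dependent and the real selection is done by the published
thresholds anyway — identity > 0.60 and query coverage > 0.60, both
strict. "Identity" means matches over aligned columns of the reported
local alignment; "coverage" is the aligned fraction of the query. Multiple
copies per window are found by best-first masking. Overlapping hits of the
same query/contig/strand (≥ 50 % of the shorter) are merged keeping the
higher score.

Iterative mining re-queries each genome with extracted copies covering
≥ 90 % of their query, until no new genomic interval appears (or a round
cap, default 3). Seed windows whose only signal is an already-accepted
interval are skipped; whole-contig windows are never skipped, because they
may still hold a second, undiscovered copy.

The family screen (Tc1/maT/GT/VS) flags a family present when any hit
reaches identity ≥ 0.30 and coverage ≥ 0.15. Under an internal aligner the
identity floor is nearly vacuous (reported local alignments rarely fall
below ~0.55); the effective rule is "an alignment-worthy hit covering
≥ 15 % of the family consensus", which is the intent of a
"no good hits" absence call.

## Terminal structure

TIR pairs are found by exhaustive enumeration over the two 60 bp terminal
windows: all (5' prefix, 3' suffix) substring pairs of length 13–32 whose
3' copy reverse-complements the 5' copy within a 15 % mismatch budget.
The selection objective is **maximize matches − mismatches**, then fewest
mismatches, then longest, then leftmost. A longest-first objective was
rejected deliberately: with a 15 % budget it always absorbs adjacent bases
into the repeat (any 28 bp perfect TIR loses to a 32 bp extension with ≤ 4
mismatches), and a TA duplication on both flanks extends every true TIR by
two exactly matching columns, shifting the boundary by 2 nt.

Hit intervals are refined to element boundaries by enumerating TIR pairs
in the padded hit region (± 45 bp) and ranking candidates by TSD support
first (TA on both implied flanks > one > none), then by the TIR objective;
the implied span must cover ≥ 80 % of the hit. TSD support must lead for
the same reason the TSD extends the repeat: repeat scoring alone cannot
distinguish the transposase-defined boundary from the TSD-extended one.

Completeness: complete iff a TIR pair is found. Otherwise each end is
tested one-sidedly with a fuzzy (Hamming, ≤ 20 %) search for the best
query's own TIR, giving truncated_5p/3p/both; a missing end within 32 bp
of a contig boundary sets `at_contig_end`. Candidates shorter than 1000 bp
are discarded (the published retention rule). The TSD is read on the 2 nt
immediately outside the element — TA duplicated by insertion — never
inside the TIR; a flank beyond the contig edge reports False.

Per-subfamily TIR consensus is the column majority of member 5' TIRs
(alphabetical tie-break); members with identity ≤ 0.85 to the consensus
are flagged, matching the expectation that same-subfamily TIRs share
> 85 % similarity.

## Transposase analysis

Six frames are translated (standard code); the longest ATG-initiated,
stop-terminated ORF wins (ties: + strand, lower frame, leftmost). When no
ORF reaches 310 aa, the element is treated as decayed: the coding frame is
the one with the **fewest in-frame stops** (a decayed transposase frame
carries a handful, the other five frames of a ~1.3 kb element dozens),
ties broken by the longest stop-free run. Premature stops are the in-frame
stops between the first ATG and the expected terminator — the first stop
at ≥ 310 codons from that ATG; if no stop reaches that distance, every
stop within a 345-codon window counts. This anchors the count to the
ORF the element is expected to encode instead of counting stops in
untranslated sequence.

The activity call is: **potentially_active** iff complete (both TIRs) and
intact ORF (no premature stop, no suspected frameshift, 310–345 aa) and
DD34D triad; **intact_orf_truncated** iff the ORF is intact but the
element is truncated; otherwise **inactive**. The 310–345 aa gate is the
active-copy range; the family-wide 282–350 aa range is recorded as a soft
annotation flag only. Motifs beyond the triad never gate activity:

* triad: positions i < j < k with the spacing constraint binding j,k
  exactly (34 for DD34D; 34E/37D/39D/41D classify the other families);
  a spaced pair without an upstream first aspartate is "degenerate";
* WVPHEL / YSPDL: best Hamming window, ≤ 2 substitutions, no indels;
* HTH: two 10-aa windows with hydrophobic residues at helical-wheel
  positions {0,3,4,7}, separated by a 3–5 aa turn containing G or P,
  within the N-terminal 120 aa — a positional heuristic standing in for a
  profile-database search, annotation-only;
* NLS: the 16-aa window maximizing K/R count, reported at ≥ 6 — a
  basic-residue heuristic standing in for a dedicated NLS predictor,
  annotation-only (many decayed and even some active copies lack an NLS).

Frameshift surrogate: the element's three forward-frame translations are
locally aligned to the best query's transposase; a frameshift is suspected
when no single frame covers ≥ 80 % of the reference but two frames
jointly do (each ≥ 15 %). It runs only when the ORF already shows stops,
as a corroborating annotation.

## Subfamily assignment

Whole-sequence identity uses the **global** affine-gap alignment path with
terminal gap runs excluded from the column count (end-gap-free identity).
The path is the penalized global optimum on purpose: a free-end-gap path
of two unrelated sequences can collapse onto a tiny perfect overlap whose
"identity" is 1.0, which would break any identity threshold; forcing the
full-length path makes identity of unrelated pairs land near 0.5 while
truncated homologs still score correctly because their overhang columns
are excluded from the count.

The identity rule assigns the best-matching labeled reference's subfamily
at ≥ 0.80, with a TIR fallback (element 5' TIR vs the subfamily TIR
consensus, ≥ 0.80) for decayed copies. The clade rule builds a
center-star MSA (center = argmin summed edit distance, computed with
edlib; all alignments to the center by the package's global aligner;
"once a gap, always a gap" merging), a distance matrix (p, JC69 or K2P —
default K2P; saturated values fall back to a large constant plus the
observed p-distance so they stay finite, deterministic and monotone), and
canonical neighbor joining (exact on additive matrices; negative branch
lengths clamped to zero; row-major argmin for deterministic ties). The
tree is rooted at the midpoint of the outgroup branch. Bootstrap resamples
MSA columns (weighted count reformulation, so each replicate is a set of
matrix products), re-runs NJ and maps bipartition frequencies onto the
main tree; the default pipeline uses 200 replicates (desk scale), 1000 by
flag. Each element's final label is the identity-rule label when present
(method "both" when the smallest label-homogeneous reference-containing
clade agrees), else the clade label, else unassigned; clades mixing
reference labels yield a conflict flag. NJ on K2P replaces a full
maximum-likelihood search because the tree is consumed only for clade
grouping, which NJ preserves at the divergences involved — the
grouping-relevant structure, not branch-length optimality, is what the
assignment uses.

## Synthetic benchmark

The generator builds, per subfamily, a consensus element: TIR + 5' UTR +
ATG-initiated ORF + 3' UTR + reverse-complement TIR, with the protein
carrying HTH, WVPHEL, DD34D, YSPDL and an NLS at fixed positions. Copies
are planted into i.i.d. background contigs at GC ≈ 34 % (the ballpark of
the target assemblies), with explicit TA TSDs, ~40 % of mid-contig copies
on the minus strand, and spacing ≥ 2 kb.

Constructional guarantees that make the truth exact, and their cost in
realism:

* consensus proteins draw background residues from an alphabet without
  D/E/K/R/W, so the planted triad is provably unique, the NLS is the only
  basic window and WVPHEL cannot arise by chance — real transposases are
  not depleted in these residues;
* TIRs are drawn free of the TA dinucleotide (an internal TA would let an
  inward-shifted sub-pair of the TIR mimic a TA-flanked boundary) and
  TIRs plus ten "guard" bases inside each TIR are never mutated, with the
  guards chosen non-complementary so the repeat cannot extend inward —
  hence detected TIR length and element boundaries are exactly the
  planted ones; real decayed TIRs do accumulate mismatches (the detector's
  15 % budget is exercised by unit tests instead);
* the 5' UTR ends in an in-frame stop and the prefix contains no in-frame
  ATG, so the first ATG of the coding frame is the planted start;
* intact copies receive synonymous-only substitutions (2 % of positions);
  decayed copies receive stop-free substitutions (8 %) plus exactly the
  planned TAA premature stops, optional third-aspartate knockout (D→N),
  optional single-base frameshift deletion, optional NLS ablation;
* truncations clip through one TIR (keeping ≥ 1000 bp); most truncated
  copies sit flush at a contig end, the dominant real-world cause.

The default configuration plants the published seven-species count
structure exactly (totals 33/26/16/10/10/10/16 = 121; per-species
subfamily splits; five potentially active copies — three in the
*K. rhusicola* analogue (one *Drosophila*, two *Mauritiana*), one
*Drosophila* each in the *M. flavogallis* and *F. choui* analogues; two
intact-ORF 5'-truncated *Drosophila* copies in the *S. chinensis*
analogue; two complete copies with TA only at the 3' end in the
*K. rhusicola* analogue; 106 complete / 15 truncated). Subfamily
consensi are generated independently, which puts cross-subfamily identity
around 0.55–0.70 — above the 60 % mining floor for some pairs (so
cross-subfamily hits occur and are deduplicated by interval, as with real
data) and safely below the 80 % subfamily rule. Genomes total ~10 Mb
(two ~650 kb host contigs, one dedicated contig per contig-end truncation,
~150 sub-kilobase background contigs per genome), a deliberate desk-scale
stand-in for the hundreds-of-Mb originals.

**What passing the benchmark shows** — that every stage implements its
rule correctly and that the stages compose: planted copies are recovered
with exact boundaries, classified, and counted back into the published
table structure with recall = precision = 1. **What it does not show** —
performance on real genomes: no segmental duplications or low-complexity
sequence to cause spurious hits, no nested or fragmented (< 1 kb)
elements, no sequencing/assembly error, motif uniqueness by construction,
and divergences well inside the thresholds rather than straddling them.

## Determinism and sizes

All randomness flows from explicit integer seeds (generation and bootstrap
both); two runs with the same seed produce byte-identical outputs, which
is asserted in the tests. Default problem sizes — ~10 Mb benchmark,
200-replicate bootstrap, 60 bp TIR windows, k = 12 — are the package's
desk-scale defaults; every one is a parameter on `PipelineParams` or the
generator configuration.

## Known limitations

* The score-floor E-value proxy is uncalibrated; sensitivity at the 60 %
  identity boundary differs from any particular search engine's.
* One-sided TIR detection needs a full-length query's TIR as reference;
  with a panel of truncated queries, truncated_5p/3p cannot be told apart
  (they fall back to truncated_both).
* The HTH and NLS heuristics are positional/compositional surrogates and
  should not be compared to profile- or predictor-based annotations.
* MITEs and sub-kilobase degenerate fragments are out of scope by design
  (the ≥ 1000 bp retention rule).
* Identity-rule and clade-rule precedence is fixed (identity first) with
  agreement recorded, since per-element precedence in the underlying
  survey methodology is not specified.
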