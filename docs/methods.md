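# Methods

This note records the models, default parameters, numerical choices and
limitations behind `secretile`, in the order the pipeline runs.

## Proteome tiling

A protein of length *n* is sliced into windows of fixed length *L*
(default 32 residues) at starts 1, 1+*s*, 1+2*s*, … with step
*s* = *L* − *v*, where *v* is the overlap between neighbouring windows
(default 14, so *s* = 18). If the last regular window ends short of the
C-terminus, one additional window anchored to end exactly at residue *n* is
emitted and flagged `is_terminal_anchor`. Anchoring, rather than padding or
truncating the final window, keeps every tile at the same synthesis length —
a hard constraint of array-based oligo pools — while preserving complete
residue coverage. The overlap guarantees that every linear epitope of up to
*v* + 1 residues (15 at defaults) lies intact inside at least one tile; this
bound is tight and is verified exhaustively in the tests.

Choices where the procedure was genuinely open:

- **Coordinates** are 1-based inclusive, matching residue numbering in
  sequence databases; library FASTA headers state this.
- **Short proteins** (< *L* residues) are skipped with a logged warning by
  default; an `emit_full_length` policy emits the whole protein as one short
  tile for completeness studies.
- **Non-standard residues** (X, U, B, Z …): any window containing one is
  dropped and tallied in the design QC — a synthesis-bound library cannot
  encode ambiguity codes.
- **Deduplication** collapses exact amino-acid duplicates across the
  proteome, keeping every origin in a provenance list; it is sequence-level
  only, so coverage accounting still credits all source proteins.

Library size depends entirely on the input proteome; the package makes no
assumption about which secretome (or other) FASTA is supplied, and the test
fixtures use uniform-random synthetic proteomes.

## Oligo design

Each tile is reverse-translated by weighted-random codon sampling from an
embedded human codon-usage table (weights normalised per residue;
configurable). Weighted sampling rather than best-codon assignment prevents
the 14-residue overlaps between neighbouring tiles from producing long
identical nucleotide stretches, which both synthesis vendors and Illumina
cluster calling handle poorly. A single RNG seeded from the cloning config is
threaded through the library in order, so the oligo pool is byte-reproducible.

The insert is cloned by Gibson assembly into a vector opened with BsrGI and
PstI, so the coding sequence — and both junctions with the assembly arms —
must not contain either recognition site (TGTACA, CTGCAG) on either strand.
Scrubbing is greedy left-to-right: for the leftmost motif occurrence, all
synonymous combinations of the codons it overlaps are enumerated
exhaustively (≤ 3 codons, ≤ 216 combinations), preferring the fewest codon
edits and then higher-usage codons; a combination is accepted only if it
removes the occurrence without increasing the total motif count. The
procedure is deterministic, verified against exhaustive enumeration on
dipeptide cases, and raises a clear error for the rare junction/codon
combinations that admit no synonymous fix (e.g. an arm ending in TGTA
followed by a histidine codon).

Both strands are always scanned. Arm sequences are user configuration — they
depend on the destination vector — and arms containing a forbidden motif are
rejected at load.

## Screen simulation

The simulator generates the data-generating process the deconvolution
assumes, with every stochastic step seeded:

1. **Integration.** Each of `n_cells` cells receives a Poisson(MOI) number
   of integrations (default MOI 0.3); integrated tiles are drawn uniformly
   with replacement, or from supplied abundance weights. At MOI 0.3 the
   infected fraction is 1 − e^(−0.3) ≈ 0.259 and ≈ 85.9 % of infected cells
   carry exactly one integration; both closed forms are recovered within
   Monte-Carlo error in the tests.
2. **Sorting.** GFP positivity is a per-cell Bernoulli: probability
   `p_gfp_active` (default 0.9) if any integrated tile is a designated
   activator, else `p_gfp_background` (default 0.01). This binary gate is
   the simplest abstraction of sorting a CRE-GFP reporter population; no
   fluorescence-intensity distribution is modelled. Cells with several
   integrations are treated as activated if any cargo is an activator
   (dominant reporter activation). The sorted pool is the tile multiset of
   GFP-positive infected cells; the naive reference pool is either all
   infected cells (default) or the uniform plasmid library.
3. **Sequencing.** Per-tile read counts follow a Dirichlet-multinomial over
   pool frequencies with concentration fᵢ / `pcr_dispersion`
   (`pcr_dispersion` → 0 recovers the plain multinomial), the standard
   overdispersion model for PCR-amplified pooled screens. Reads are the
   arm-flanked insert truncated (or A-padded) to `read_length` (default
   150 nt) with i.i.d. substitution errors at `seq_error_rate` (default
   10⁻³); quality strings are constant Phred 40. Base-quality profiles,
   paired ends and index hopping are not modelled.

The synthetic proteome generator draws residues uniformly from the 20
standard amino acids. It reproduces the combinatorial structure the pipeline
operates on (unique windows, realistic lengths) but none of the composition
biases, repeats or paralogy of a real secretome — so passing tests
demonstrate correctness of the machinery, not performance on adversarially
repetitive gene families, where ambiguous-match discards would rise.

## Deconvolution and enrichment

Reads are trimmed by locating the constant 5′ flank with at most
`max_flank_mismatches` substitutions (default 1) and taking the following
`insert_length` bases. Inserts are matched in three tiers: exact nucleotide
match to the designed CDS set; exact amino-acid match after translation
(absorbing synonymous divergence between designed and resequenced codons);
then nearest CDS within `max_nt_mismatches` (default 1) substitutions,
discarded if the nearest neighbour is not unique. Discarding ambiguous
near-matches is conservative and deterministic; fractional assignment is
deliberately avoided. Every read lands in exactly one bucket (a tile or a
categorised rejection), an invariant asserted at run time.

Enrichment of each tile is scored on the 2×2 table
(c_s, N_s − c_s; c_n, N_n − c_n) of sorted/naive read counts with a
one-sided Fisher exact test (implemented as the hypergeometric upper tail
and cross-checked against an independent Pascal-triangle enumeration on all
tables with N ≤ 200), Benjamini–Hochberg FDR across tiles, and a log2
fold-change of pseudocounted frequencies (pseudocount 0.5). A hit requires
q < 0.05 and log2FC ≥ 1. These thresholds follow common pooled-screen
practice and are exposed as parameters; ranked q-values, not the binary
flag, are the primary output.

**Known caveat.** Fisher on read counts treats reads as independent, but
when the sorted pool contains few cells, many reads resample the same
integration event and the test is anticonservative: background cells that
happen to sort GFP-positive can reach small q-values (visible in the README
example). Sorting more cells, sequencing to a depth commensurate with the
sorted-cell count, or replicate sorts mitigate this; replicate-aware
modelling is out of scope.

## Dose–response fitting

The 4PL model y = bottom + (top − bottom)/(1 + (EC50/x)^hill) is fitted by
trust-region least squares with EC50 parameterised as log10(EC50), bounded
to the observed dose range widened by three decades per side. Multi-start
initialisation covers plateau estimates from the response extremes (both
orientations, so inhibition curves fit without special-casing), a
three-point EC50 grid over the dose quantiles, and Hill slopes {0.5, 1, 2}.
Optimiser tolerances are set to 10⁻¹³ so the fitted EC50 is invariant to
rescaling the response axis to better than 10⁻⁸ relative — important
because HTRF data may enter as raw (665/620) × 10⁴ ratios or as normalised
percent responses. Standard errors come from the Gauss–Newton covariance at
the optimum; degenerate inputs (constant responses, fewer than five distinct
doses, non-positive concentrations) raise immediately rather than returning
a meaningless fit.

Estimator quality is characterised by `ec50_recovery_study`: 200 synthetic
curves at a given potency, 8 log-spaced doses spanning 4 decades centred on
the generative EC50, 3 replicates per dose, 5 % multiplicative CV. Under
these conditions the median fitted EC50 is within a few percent of truth and
the log10(EC50) bias is below 0.01; these are the conditions
`scripts/acceptance.py` re-runs at the validated peptide potencies. The
dose design (4 decades centred on the true EC50) is favourable; curves whose
EC50 lies near the edge of the tested range would recover with more bias
and variance.

## Problem sizes used in the test suite

Simulation-backed checks use 10⁵ cells for the Poisson statistics, a
~1000-tile library with 5 planted activators, 2 × 10⁵ cells and 10⁵ reads
per pool for end-to-end recovery, and 200 curves per potency for EC50
recovery — sizes at which the Monte-Carlo error bands in the assertions are
comfortably resolved.
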