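# Methods

## The library model

The synthetic HCDR3 is nine residues, encoded by the degenerate codon
template (NNS)₆ KBG HTK GMT (IUPAC codes: N = ACGT, S = CG, K = GT,
B = CGT, H = ACT, M = AC). NNS covers all twenty amino acids and the amber
stop TAG while excluding TAA/TGA; the last three codons restrict positions
7–9 to the subsets those templates can encode (position 9, GMT, reaches
only Asp and Ala). Translation uses the standard code with TAG read as Gln,
modelling the suppressor host; TAA or TGA anywhere makes a sequence
invalid, as does any ambiguous base.

In the amplicon the insert sits between two literal anchors. The study that
motivated this design gives the flanking regions as amino acids only
(Val-Arg-Glu containing the BsiWI site upstream; a fixed Tyr plus the WGQGT
framework-4 consensus before an XbaI site downstream), so the package fixes
one concrete nucleotide choice as a documented fixture:

- upstream: a 12-nt primer stub + `CGTACGTGAG` — the BsiWI site `CGTACG`
  followed by GTA·CGT·GAG = V·R·E. An in-frame V-R-E 9-mer cannot contain
  `CGTACG` entirely (checked by enumeration), so the site overlaps the base
  preceding the V codon; the anchor is 22 nt.
- downstream: `TAT` (Tyr) + `TGG GGT CAG GGA ACC` (W G Q G T) + `TCTA`
  (start of the XbaI site); 22 nt.

With the default 6-nt barcodes (`ACGACG`, `CGTCGT`, `GTAGTA`, `TACTAC`,
pairwise Hamming distance 6) the amplicon is 6 + 22 + 27 + 22 = 77 bp, the
amplicon length of the assay being emulated. Reads are emitted at amplicon
length rather than padded to the instrument's 150 cycles: the overhang past
the amplicon is vector sequence the analysis never touches.

## The simulator

`make_initial_pool` draws `n_variants` distinct 27-mers uniformly from the
template expansion; they share `1 − dominant_mass` equally. Each dominant
peptide is represented by several synonymous encodings (default 8, or all
of them if fewer exist), and all dominant encodings together share
`dominant_mass` equally. The defaults — two dominant peptides at 96.7% of
the round-0 mass — reproduce the regime in which a couple of
over-represented clones, each coded by multiple nucleotide sequences,
dominate the unselected library.

`apply_selection` is deterministic multiplicative selection: one round maps
f(v) ↦ f(v)·w(peptide(v)) / Σ f·w. Without a bottleneck, r rounds equal the
closed form f·wʳ (tested against that oracle). An optional multinomial
bottleneck of B draws after each round models the finite phage titer
carried between rounds; variants drawn zero times disappear. The default is
three rounds, matching the panning protocol emulated (one supplementary
description mentions four; three is what the protocol and the sequenced
pools used, so three is the default and `rounds` is a parameter).

Each V-gene context receives its own random log₂-uniform fitness in
[−2, 2] (fold-change ratios 0.25–4 per round), except that the first
dominant peptide is favoured (w = 2) in the vh10 context and disfavoured
(w = 0.5) in vh4, and vice versa for the second — the two dominant clones
move in opposite directions under selection, as observed.

`emit_reads` samples a variant per read, builds the amplicon, and applies
i.i.d. substitution errors (default 0.5% per base, a typical HiSeq rate) to
R1 and, independently, to the reverse-complemented strand for R2. Bases
carrying an injected error receive the low quality score (Q2), all others
the high score (Q40), so a failed extraction is always attributable.
Errors are substitutions only; the analysis keys on fixed-length exact
matches and the platform's dominant error mode is substitution. Indels can
be exercised through the anchor-destruction utility instead. All draws come
from one seeded generator consumed in per-read order, so raising the depth
appends reads without changing earlier ones, and identical configurations
give byte-identical FASTQ.

What the simulator does **not** model: PCR amplification bias and chimeras,
quality-score/error-rate coupling beyond the two-level scheme, cluster
cross-talk, or any deviation of the real library from its design template.
Passing the closed-loop tests therefore shows the pipeline's bookkeeping is
exact and its statistics are correctly computed — not that real libraries
conform to the theoretical scheme (observed libraries demonstrably deviate
from it, which is why scheme conformity is never enforced on extracted
HCDR3s; a valid HCDR3 is: length 27, unambiguous bases, no unsuppressed
stop).

## Pipeline rules and parameters

- **Quality policy**: mean Phred ≥ 20 and min base ≥ 10, inclusive, over
  the whole read by default (an HCDR3-window variant is available); N bases
  count as Phred 0. The emulated study states only that reads were quality
  filtered; these are conventional values, and the validation suite either
  disables errors or asserts threshold-independent properties.
- **Barcodes** are prefix-anchored (the barcode is the amplicon's leading
  sequence). Assignment allows `max_mismatch` substitutions (default 1) and
  requires pairwise barcode distance > 2·max_mismatch, which makes ties
  within budget impossible; the tie rule (two barcodes at equal minimal
  distance → unclassified) is retained as defensive logic.
- **Extraction** requires both anchors to occur exactly once, in order,
  exactly 27 nt apart — the perfect-match rule. A configurable relaxation
  does not exist by design; fuzzy recovery would change what "valid HCDR3"
  means.
- **R2 fallback**: R2 (reverse-complemented into amplicon orientation) is
  consulted only when R1 was discarded for low quality or match failure.
  Pool assignment uses whichever mate was actually consulted. A pair whose
  R1 extracts cleanly but matches no barcode is unclassified without
  consulting R2.
- **Fold change** defaults to frequency normalization (counts divided by
  pool totals) because sequencing depths differ several-fold between
  pools; the literal count ratio is `normalize=False`. Pseudocount default
  0; peptides absent from round 0 go to a separate *novel* list rather than
  receiving an inflated ratio, and peptides absent from round 3 get FC = 0
  and appear in *lost*. A minimum round-0 count (default 1) guards
  singleton blow-up. Strata default to exclusive bands [4,7), [7,10),
  [10,∞) and mirrored counter bands, boundaries inclusive on the selected
  side; cumulative mode is available and reports name the mode used.
- **Entropy/IC/KL** use base-2 logarithms throughout (the information-
  content convention of sequence logos). S_max is log₂ 4 = 2 bits for DNA
  and log₂ 20 ≈ 4.32 bits for protein, i.e. a uniform residue frequency of
  1/20 = 0.05. No small-sample logo correction is applied by default; with
  10⁴–10⁵ sequences per pool it is negligible.
- **KL smoothing**: both rounds' positional distributions are smoothed by
  adding the pseudocount (default 0.5) to each symbol's effective count and
  renormalizing. A zero in the reference where the observed round is
  non-zero is an error directing the user to a positive pseudocount;
  symbols absent from both distributions contribute nothing (the divergence
  is computed on the shared support rather than rejected outright, since
  error-free data legitimately leaves whole columns empty in both rounds).
- **Weighting**: logos, entropy and KL default to unique weighting — each
  distinct sequence counts once — matching the convention that peptides are
  not weighted by their frequency when profiling diversity. Count weighting
  is a flag. One deliberate exception: the restrictive-vs-permissive
  divergence contrast in the validation suite uses count weighting, because
  at depths where every variant is still observed at least once the unique-
  weighted matrices of the two rounds coincide and the statistic measures
  nothing; the composition shift is the phenomenon of interest there.
- Positions are 1-based in all outputs (nucleotide 1–27, residue 1–9).

## Determinism and problem sizes

Every output table carries the run seed and a digest of the configuration;
reruns with identical configuration are byte-identical (dictionary
iteration is insertion-ordered and all tables are explicitly sorted). The
validation suite runs the closed loop at 4 × 25,000 error-free pairs, the
rescue experiment at 40,000 pairs with 10% anchor destruction, selection
recovery at 200 peptides × 10⁵ reads per round, the divergence contrast
over 100 seed replicates, and the determinism check at 4 × 10⁵ pairs with
errors — sizes chosen so the full suite completes in well under a minute of
compute while keeping multinomial sampling error far below the effects
being measured.

## Known limitations

- Peptide-level tables fold suppressed-amber Gln together with CAA/CAG
  Gln; the nucleotide tables preserve the distinction.
- No denoising or clustering of near-identical sequences: a sequencing
  error that survives the quality filter becomes a (rare) spurious unique
  sequence, exactly as in the emulated analysis.
- No significance testing of enrichment; fold change is reported as-is.
- Count tables written to disk keep sequences and counts only; rebuilding
  `PoolCounts` from a TSV (as the stage-wise `enrich`/`diversity`
  subcommands do) loses the R2-provenance counters, which live in the
  classification and unique-sequence reports instead.
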