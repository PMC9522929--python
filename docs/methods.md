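# Methods

## Molecule counting model

The unit of observation is the inferred cDNA molecule: a unique
combination of UMI (12 nt), assigned V segment, and junction nucleotide
sequence.  The junction runs from the first base of the V segment's
conserved C-terminal cysteine codon (TGT/TGC) through the last base of
the J segment; constant-region bases are excluded.  The CDR3 is the
prefix of the junction ending at the J segment's conserved phenylalanine
codon (TTT/TTC, the F of the F-G-X-G motif) inclusive, so an in-frame
CDR3 has length ≡ 0 (mod 3).  Clonotypes are (V, junction) classes; the
clone size of a clonotype is its number of distinct UMIs, treated as a
proxy for the number of contributing mRNA molecules and, ultimately,
cells.

Two assumptions follow from the chemistry and drive the design:

- UMIs are attached before amplification, so read counts within a UMI
  reflect amplification/sequencing depth, not biology; all abundance
  statistics use UMI counts.
- The paired mates are never assembled.  The UMI-side mate determines the
  UMI and the V call (by ungapped seed-and-extend identity, acceptance at
  ≥ 0.90 identity over ≥ 30 nt, lexicographic tie-break); the
  constant-side mate, reverse-complemented into transcript orientation,
  determines the junction.  If the called V's germline tail cannot be
  located upstream of the J in the 3' fragment, the observation is
  rejected rather than reassigned, keeping the two mates' roles separate
  and failures visible in the parse statistics.

## Anchor conventions

Anchors are primary data: germline references are loaded from FASTA plus
a two-column TSV of 0-based anchor-codon offsets, validated against the
Cys/Phe codon invariants.  `detect_anchor` is a deterministic fallback:
for V, the last TGT/TGC codon within the final 15 nt, scanned
left-to-right without overlap (the TGC nested inside the common
`TGTGCC...` cysteine context would otherwise shadow the true codon); for
J, the first TTT/TTC opening the 12-nt motif `(TTT|TTC)GG.{4}GG.`
(F-G-X-G), falling back to the first TTT/TTC when the motif is absent.
Coordinates are 0-based half-open internally; IMGT gap dots are stripped
on input.

## Junction delimitation

The J is located by matching J suffixes (5'-trimming allowed down to,
but never into, the Phe codon) against the 3' fragment: candidates are
ranked by (mismatches, trim, J id), exact matches first, then an
approximate infix search (edlib, k = 1).  Ranking mismatches before trim
means a rearrangement that truly trimmed one J base is preferred over a
full-length J alignment that needs an error to fit.  The V cysteine
position is then fixed by locating a ≥ 12-nt window of the V germline
tail (for each candidate 3' trim) upstream of the J, exact first, then
≤ 1 error; the window-to-anchor offset makes the inferred Cys position
independent of which trim variant matched.

Mismatch tolerances (TSO anchor ≤ 1; GSP ≤ 1; J ≤ 1; V tail ≤ 1;
V identity ≥ 0.90) are implementation choices, set so that error-free
reads parse exactly and reads at realistic substitution rates (0.1–1%)
usually survive; all are exposed as function parameters.

## Error collapse

Two rules, applied in order:

1. `filter_min_reads` — a molecule record is kept only with
   `read_count ≥ min_reads` (default 2).
2. `merge_errors` — records are processed in descending read-count order
   (ties broken by key); each record is absorbed by the first
   already-retained record within Hamming distance ≤ 1 on the UMI *and*
   Levenshtein distance ≤ 2 on the CDR3 (and, by default, an identical V
   call — a near-duplicate with a different V is a V-assignment
   ambiguity, not a sequencing error).  Absorbed read counts are added
   to the retained variant by default (`absorb_reads`), conserving total
   reads.

Hamming is used for UMIs (fixed length 12), Levenshtein for CDR3s
(variable length).  Both conditions are required jointly.  The greedy
pass is order-of-input invariant because of the sorting contract, never
increases the record count, and is idempotent whenever the retained set
is mutually non-mergeable.  `brute_force_collapse` recomputes the result
from the full pairwise distance matrix (≤ 500 records) and serves as an
independent oracle; the production implementation accelerates candidate
lookup with a Hamming-1 UMI neighbourhood index but must (and does)
agree exactly.

## Significance testing

`ttest_two_sided` reproduces the conventional two-stage recipe: a
two-sided F-test on the sample variances at α = 0.05 chooses between the
pooled and Welch t statistics; p-values are two-sided;
`p_bonferroni = min(1, p × n_comparisons)`.  If exactly one sample has
zero variance the Welch branch is used (the F-test is undefined but the
statistic remains well-posed); two zero-variance samples are rejected as
degenerate.  The statistic itself is delegated to scipy; the test-suite
checks both branches against statsmodels to 1e-10.

## The synthetic library

`tcrumi.simulate` emulates the 5'RACE-UMI architecture:

- UMI-side mate: random stagger (4–7 nt) + universal primer
  `CTAATACGACTCACTATAGGGC` + TSO anchor `AAGCAGTGGTATCAACGCAGAGT` +
  split UMI block `N4-T-N4-T-N4-T` + `CTT` + `GGGGG` + transcript 5'
  end.  The three uracils of the physical oligo are sequenced as T; the
  UMI is the 12 N bases.
- Constant-side mate: stagger + constant-region GSP2 (`GGAGTCACATTTCTC
  AGATCC` for Tcrb, `CAGGTTCTGGGTTCTGGATGT` for Tcra) + the reverse
  complement of the transcript, covering a short constant stub, the
  entire J, the junction and the V 3' end.
- Reads are 300 bp, truncated from the template; qualities are constant
  Q30 because the pipeline's rules are count-based.

Junctions are built as V tail (0–3 nt trimmed, never into the Cys) +
geometric(p = 0.25) random insert (truncated at 12 nt) + J (0–3 nt
trimmed from the 5' end, never into the Phe).  Each clone's frame class
is drawn once (Bernoulli with the configured out-of-frame fraction) and
the insert length nudged by 1–2 nt to land in that class; the class is
held fixed across junction-uniqueness retries so that collisions among
short-insert junctions cannot bias the realized fraction.

Clone abundances follow a uniform, Zipf(s), or lognormal law over a
latent pool of `n_clonotypes` clones; molecules are assigned
multinomially, so the pool may exceed the molecule count — a diverse
naive repertoire is far larger than the number of captured mRNAs, and
clones that draw no molecules simply do not appear.  Per-molecule read
depth is `min_depth + Poisson(depth_mean − min_depth)` (defaults 2 and
10: amplicon sequencing yields many more reads than molecules).
Substitution errors come in two layers: a PCR pass applied once per
amplified copy (shared by the two mates of a read pair, independent
between pairs; default 5 × 10⁻⁴/base) and i.i.d. per-base sequencing
errors (default 2 × 10⁻³/base).  No indels, chimeras or quality-score
structure are modelled — the pipeline's rules are substitution- and
count-based, so these axes would not change what the tests probe.

What passing tests show, and what they do not: the simulator shares the
pipeline's sequence vocabulary (toy germline of 4 V × 3 J per locus,
exact layout constants), so recovery tests demonstrate the correctness
of parsing, delimitation, counting and collapse under the stated error
model — not robustness to real-world artefacts such as indel errors,
mispriming, chimeric amplicons, allele-level germline variation, or
cross-sample contamination.

### Study-condition defaults

Two contrasts used throughout the tests are fixed as package defaults:

- Frame purge: thymus-like samples use an out-of-frame clone fraction of
  0.12; spleen-like samples 0.0 (peripheral selection removes
  non-functional rearrangements).
- Clone-size contrast: the diverse ("wild-type-like") condition is a
  uniform law over a pool of 5× the molecule count — Poisson occupancy
  with λ = 0.2 gives an expected singleton fraction
  λe^{−λ}/(1 − e^{−λ}) ≈ 0.906; the expanded ("mutant-like") condition
  is Zipf s = 1.5 over a 10× pool, whose expected singleton fraction
  evaluates numerically to ≈ 0.65.  These land the two conditions near
  the 0.90 vs 0.65 singleton split characteristic of a diverse versus a
  homeostatically expanded peripheral repertoire, and were chosen from
  the occupancy formulas, not fitted to simulation output.

## Genotyping utilities

`insilico_pcr` finds the forward primer on the plus strand and the
reverse primer as its reverse complement downstream; the amplicon spans
the forward primer start through the end of the reverse site, and any
priming ambiguity (0 or > 1 product) is an error, never a guess.
`apply_tg_at_mutation` scans the longest ATG-initiated ORF for the
unique CTG codon in plus-strand hexamer context GCTGGC; the TG>AT
substitution converts the hexamer to the SphI site GCATGC and the codon
to CAT (Leu→His), changing exactly two nucleotides.  `digest` cuts after
the fifth base of each GCATGC on the top strand; fragment lengths ignore
overhang chemistry (± 2 nt is irrelevant at gel resolution, but the
convention is fixed).  ORF search is plus-strand only (the input is an
mRNA-derived cDNA); ties go to the leftmost ORF.

`synthetic_transgene_cdna` is a deterministic, clearly labelled
synthetic stand-in for the Gtf2i delta-isoform cDNA, built to the assay
geometry (880 bp amplicon between the OBG_7/OBG_14 priming sites, the
mutable Leu at residue 384 of a 419-residue ORF, SphI cut 320 bp into
the amplicon, wild-type amplicon free of GCATGC) and validated end to
end at construction.  It exercises the tool-chain offline; analyses of
the real GenBank record simply pass its FASTA via `--template`.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale instances chosen as the smallest
sizes at which the statistical assertions have comfortable margins:
500 clonotypes / 5,000 molecules for the exact round trip, 2,000
molecules at realistic error rates for recovery, 20,000 molecules for
usage recovery (total-variation < 0.02), 100 random instances for the
collapse oracle, 5 replicate pairs for the frame contrast, 20 seeded
pairs for the clone-size contrast, and 1,000 random cases for the t-test
reference check.  Determinism: all sampling flows through a single
`numpy.random.default_rng(seed)`; identical configurations produce
byte-identical FASTQ.  Sorting contracts (descending count, then
lexicographic key) make every tabulation and merge independent of input
order.

## Known limitations

- No indel-aware alignment anywhere in the extraction path; an indel
  sequencing error shifts the junction and is rejected or miscounted
  (then filtered or merged).
- No probabilistic UMI consensus (directional networks, Bayesian
  collapse); the greedy rule is the published two-threshold rule.
- Usage fractions are per-clonotype and unweighted; no diversity indices
  beyond the clone-size histogram and singleton fraction.
- The toy germline is deliberately small and synthetic; allele-level
  nomenclature and D segments are out of scope (clonotypes are keyed on
  V and junction only).
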