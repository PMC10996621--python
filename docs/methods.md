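# Methods notes

## The problem and the model

A young ERV family is modelled by its consensus: one LTR sequence and one
internal sequence (`ErvFamilyModel`). At integration a copy has the
structure `TSD – LTR – internal – LTR – TSD`, where the target-site
duplication (TSD) is a short stretch of host sequence duplicated on both
flanks. Three later fates are modelled: ectopic recombination between the
two LTRs collapses the copy to a solo LTR (both TSD copies survive);
precise excision-like absence restores the pre-integration site with
exactly one TSD copy; and larger deletions remove the locus together with
its flanks. Because LTRs are identical at integration and copies accumulate
substitutions independently afterwards, sequence divergence — between
copies, or between the two LTRs of one provirus — measures time since
transposition.

## Synthetic genomes and what they do (not) emulate

The generator plants insertions into i.i.d. random DNA and records every
event in a truth table (0-based, half-open coordinates; one row per locus
per genome). Conventions:

* Insertion at point `p` with TSD length `t` rewrites the chromosome as
  `seq[:p+t] + element + seq[p:]`; the truth row spans the element only, so
  the left TSD copy is `[start−t, start)` and the right `[end, end+t)`.
  `ABSENT_PRECISE` removes `[start, end+t)`, which restores the original
  chromosome byte-for-byte (tested as a round trip).
* Divergence is an independent-substitution process (each site mutates with
  the given probability to one of the three other bases); no indels by
  default, since the downstream statistics are substitutions/site.
* Event positions are interpreted against the genome as it stands when the
  event is applied, which yields one-level nested insertions for free;
  truth rows spanning the insertion point are extended rather than shifted.
* `LOCUS_DELETION` removes the element, one TSD copy and `deletion_span` bp
  of flanking sequence (split evenly), so the chromosome shrinks by exactly
  `element + tsd + span`.
* The default synthetic family has a 1200-bp LTR, a 2454-bp internal region
  carrying a single 617-aa Gag ORF between an ATG-free 5′ pad and a short
  3′ UTR, and 5-bp TSDs. The LTR length is chosen so that solo LTRs survive
  the standard 1000–8750 bp length filter (that window exists precisely to
  retain partially intact solo LTRs); the TSD length is configurable
  because real families differ and 4–6 bp is typical for LTR elements.

The standard benchmark (`simulate_study`) is a 2-Mb reference (4 × 500 kb)
with 60 insertions — 40 full proviruses, 15 solo LTRs, 5 truncated copies —
at divergence uniform on [0, 2%], and three strains carrying 20 status
events (absences, solo conversions, 2-kb locus deletions) distributed over
distinct loci. Insertions are placed on a stratified grid with jitter so
spacing, not rejection sampling, guarantees non-overlap.

What the simulations deliberately lack: sequence context (real genomes are
repeat-rich, so flank anchors can be ambiguous), indels and internal
rearrangements, segregating within-strain polymorphism, and transposition
dynamics over generations. Passing the recovery suite therefore shows the
decision procedures are correct under clean substitution-only conditions,
not that the scanner would outperform RepeatMasker on a real assembly —
which is why RepeatMasker `.out` tables and minimap2 PAF files are accepted
as drop-in inputs.

## Annotation

The built-in scanner seeds exact k-mers (default 15) shared between genome
and consensus part, groups seeds per diagonal (no indels, so one diagonal
per copy), trims each diagonal to its maximum-scoring ungapped run
(match +1, mismatch −3), and rescues full-overlap hits whose whole diagonal
stays within the divergence ceiling — this recovers exact boundaries even
when the outermost consensus bases are mutated, while leaving genuinely
truncated copies trimmed at the breakpoint. Hits below 50 bp or above 15%
divergence are dropped.

Defragmentation merges same-chromosome, same-strand hits separated by at
most `max_merge_gap` (default 500 bp, configurable) when their
element-sense part order is consistent: `5′LTR → internal… → 3′LTR`,
internal fragments advancing along the consensus (40 bp slack). Two LTR
hits never merge without an intervening internal fragment, which keeps
tandem solo LTRs and back-to-back elements separate. Classification is
purely structural: `LTR (internal)+ LTR` → full provirus; a lone LTR →
solo LTR; everything else → truncated.

TSD detection returns the longest exact flank duplication with length in
[2, 20] bp; "longest wins" is the brute-force-equivalent definition and is
oracle-tested. Mismatched TSDs are deliberately not searched — the
empty-site evidence downstream relies on perfect duplications.

## Gag assessment

The canonical Gag ORF is located once on the family consensus by a
longest-ORF scan (ATG-initiated, stop-terminated, sense strand only —
retroviral *gag* is sense-encoded). Each copy is then read in that
canonical frame from the canonical start: a substitution creating a stop at
codon 69 yields `protein_len = 68` and a premature-stop flag, even if a
longer spurious ORF survives downstream. A copy is "intact" when the start
codon is preserved and the protein reaches ≥ 95% of the expected length
(`intact_fraction`; "full-length" is not given a tolerance in common usage,
so 0.95 is a documented choice). Protein identity uses a global alignment
with match +1 / mismatch 0 / gap open −1 / extend −0.5, free terminal gaps;
identity = matching columns / columns excluding terminal gaps.

## Recency

Copies are globally aligned to the consensus (match 2, mismatch −1, gap
open −6, extend −1, free end gaps) and projected onto consensus columns;
insertions relative to the consensus are dropped, copies covering < 50% of
columns are excluded. p-distances use shared non-gap columns (≥ 100
required, else the pair is reported missing, not zero) and are corrected
with Jukes–Cantor. The neighbor-joining implementation is the classic
Saitou–Nei agglomeration with deterministic lowest-index tie-breaking;
negative branch lengths are clamped to zero with a warning (standard
practice). It is exact on additive matrices (checked to 1e-9 on a 4-taxon
case) and cross-checked against scikit-bio's `nj` on noisy matrices.

NJ + JC is a distance-based substitute for maximum-likelihood tree
inference: the statistics consumed downstream are terminal branch lengths
(median; fraction below 0.01 substitutions/site), for which NJ terminal
branches are a proxy, not numerically identical to ML branch lengths.
Partitioned LTR/internal modelling is likewise out of scope; a single
concatenated projection is used and the output metadata says so.

## Polymorphism calling

Flank convention (this fixes all the arithmetic): the left flank ends
immediately 5′ of the left TSD copy and the right flank begins at the right
TSD copy. The expected anchored gaps are then `element + tsd` (shared
full), `LTR + tsd` (solo conversion) and `0` (precise absence, where the
single surviving TSD copy sits exactly at the junction and
`verify_empty_site` demands exactly one copy spanning it). Anchors are the
`min_anchor` bp of each flank nearest the locus, placed by exact seed
k-mers plus Hamming verification (≤ 10% mismatches), both orientations
searched; a unique best colinear placement is required — ambiguity yields
`UNDETERMINED`, never a guess. Gap tolerance is `max(50 bp, 10% of the
expected length)`; for provirus loci the shared-full and solo windows must
be disjoint under that tolerance (checked), while for solo-LTR reference
loci the two expectations coincide by construction and "shared full" simply
means "same as reference". One flank placed and the other lost maps to
`LOCUS_DELETED`; both lost or ambiguous maps to `UNDETERMINED`; the raw
evidence (gap, expectations, anchor scores, TSD check) is emitted alongside
every status so calls are auditable. Precomputed minimap2 PAF alignments
can substitute for the in-repo anchoring via `ervkit.io.read_paf`.

A locus is "polymorphic" when ≥ 2 distinct statuses occur among its
determinable cells (deleted/undetermined cells are excluded from that
determination).

## Oligo targets

The genomic site an antisense oligo acts on is its reverse complement,
searched on the element-sense strand of each copy (minus-strand copies are
reverse-complemented first — oligos act on transcripts). Matching is
substitution-only; copies whose annotated sequence is shorter than the site
are reported separately as truncated candidates rather than counted as
misses. Target counts are monotone in the mismatch allowance and satisfy
total ≥ proviral ≥ full-Gag (both tested). Gene proximity uses the gap
between closest interval edges (overlap = 0) with a ≤ 10 kb default, the
conventional window for cis-regulatory adjacency.

## Pipeline, determinism, problem sizes

All randomness flows from one top-level seed; per-stage seeds are drawn
from a generator seeded with it, and the manifest records the seed, every
threshold actually used, and a SHA-256 checksum of every output file. Two
runs with the same config are byte-identical (tested). Stage failures raise
a stage-named error; partial outputs are retained.

Default problem sizes are desk-scale choices: the demo config uses 2 ×
120 kb chromosomes and 1.5-kb flanks; the benchmark uses a 2-Mb reference,
2-kb flanks and 400-bp anchors. The 50-kb flank default on
`extract_locus`/`polymorphism` mirrors how real loci are extracted from
assemblies; only the `min_anchor` bp nearest the locus are ever used for
anchoring, so the smaller simulated flanks exercise the same code path.

## Known limitations

* The scanner assumes substitution-only divergence; indel-rich or highly
  fragmented copies should come from RepeatMasker instead.
* Strain events are applied to non-nested loci; statuses of nested pairs
  are classified against the innermost element only.
* Empty-site verification with a 0-length TSD passes vacuously and is
  flagged low-evidence.
* NJ terminal branches underestimate ML branch lengths when the molecular
  clock is badly violated; the recency fractions should be read as
  order-of-magnitude statements, as they are in practice.
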