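# Methods

## Coordinate model

All features live on the deposited plus strand as 0-based half-open
intervals. On circular genomes a feature spanning the origin keeps a single
interval with `end > genome_length`; every computation (sub-sequence
extraction, overlap, NCR complement) reads coordinates modulo the genome
length. This one rule replaces the usual special-casing of wrapped
features. Two-contig submissions joined by a placeholder run of ≥100 `N`
are kept joined; the run's start positions are recorded as `contig_breaks`
and `N` is excluded from all composition percentages and skews.

## Annotation curation

The protocol mirrors how multi-annotator mitogenome annotation is done by
hand, made mechanical:

- **tRNA acceptance.** Same-label calls are clustered into loci (same
  strand, ≥1 bp overlap; the threshold is deliberately minimal — the rule
  is agreement of identity and locus, not of exact boundaries). A locus
  with ≥2 sources is accepted with evidence `dual`; a single-source locus
  is accepted only if its dot-bracket structure contains an acceptor stem
  and an anticodon arm (`single+cloverleaf`). Requiring a full four-arm
  cloverleaf would wrongly reject the D-armless serine tRNAs, so the two
  core arms are the criterion. Span conflicts resolve by an explicit
  source-priority list, defaulting to the structure-bearing source.
  Accepted same-label loci at disjoint positions are kept and flagged
  `putative duplication`.
- **Arm detection.** Base pairs from the dot-bracket string are grouped
  into helices; helices of ≥3 pairs are stems. The outermost enclosing
  stem is the acceptor; inner stems are D/anticodon/T by 5'→3' position
  when all three are present, otherwise the anticodon arm is the stem
  whose loop lies nearest the midpoint of the acceptor-enclosed region
  (the raw sequence midpoint would be skewed by the 3' discriminator
  tail).
- **PCG boundary editing.** The start moves downstream to the first
  ATG/ATA/ATT/TTG/GTG in the called span; that codon anchors the frame.
  The end is the first in-frame TAA/TAG, or a truncated `T`/`TA` when a
  validated tRNA begins within 2 bp downstream on the coding strand (the
  stop is completed to TAA by polyadenylation; recorded `T(AA)`/`TA(A)`).
  The 2 bp window is a strict operational choice — punctuation-model
  processing leaves essentially no gap. An in-frame stop within the first
  30 codons flags the gene `pseudo?`; overlapping PCGs are legal only in
  different frames (the later-starting call of a same-frame pair is
  rejected).
- **rRNA extension.** Each rRNA widens outward to abut its nearest
  flanking accepted feature of any type — in these genomes rRNAs are
  flanked by tRNAs (trnV sits between the two rRNAs), so "extend to the
  neighbouring gene" rather than "to the adjacent PCG" is the workable
  reading. Already-abutting boundaries are untouched, making the whole
  curation idempotent.

## Descriptive statistics

Skews are computed on the deposited plus strand (per-gene variants on
coding strands); RSCU uses translation table 5 with
`RSCU_c = n_c · k / Σ n_family` and zero-usage families reported as 0.
Stop codons are tallied separately (TAA, TAG, `T(AA)`, `TA(A)`) and never
enter RSCU; a gene whose length is not a codon multiple after
truncated-stop removal is excluded from the codon pools and listed. The
NCR inventory reports every uncovered interval ≥1 bp and summarises the
conventional >10 bp and >100 bp classes; the origin-spanning gap appears
once. Overlaps are positional (plus-strand coordinates) regardless of
strand. Reports print skews to 4 decimals and percentages to 1, with
round-half-even, so repeated runs are byte-identical.

The tandem-motif scanner enumerates exact arrays (unit 6–30 bp by
default, ≥2 full copies, plus a partial tail), resolving overlapping
candidates by maximal total length, then smaller unit, then leftmost
start. The stored unit is the phase actually laid down (so
`unit × copies + tail` equals the genomic substring exactly);
`canonical_unit` exposes the lexicographically least rotation for
cross-genome comparison. Ambiguous adjacent arrays are reported
separately rather than merged into a guessed single count.

## Gene orders and rearrangement inference

Orders are circular signed permutations of the canonical 37 labels,
compared after normalisation (rotate cox1 first, flip if cox1 is on the
minus strand); no reflection is applied — strands are biologically
meaningful. When a tRNA overlaps an rRNA the tRNA precedes it in the
extracted order (the convention for tRNAs nested in rRNA boundaries).
Conserved blocks are maximal runs of adjacencies shared by all orders;
each run is a signed common interval, and a brute-force common-interval
enumeration over all circular windows is exposed separately (n ≤ 37 keeps
that trivial).

Scenario inference works on the linearised order (events never span the
cox1 anchor — the rearrangements modelled here all fall within the gene
blocks) and proceeds in three stages:

1. **Reduction.** The target is relabelled to the identity permutation
   and shared adjacencies collapse into supergenes, shrinking a 37-gene
   problem with few events to a handful of symbols.
2. **Single-event signatures.** All single events reaching the identity
   are recognised analytically from the mismatch window: one
   reversed-and-flipped window is an inversion; an edge block swap is a
   transposition (both operand readings are reported — moving X past Y
   and Y past X are distinct co-optimal events); the flipped variants are
   inverse transpositions; and a sign-clean window splitting into two
   ascending value-classes is a tdrl, one event regardless of segment
   length, with keep-first = the low value class. tdrl is directional —
   its inverse is generally not a tdrl — so costs are asymmetric and
   inference always runs ancestral → derived.
3. **Bounded search.** Deeper scenarios come from breadth-first search
   over event applications with the analytic detector as goal test:
   exhaustive successor enumeration while the reduced alphabet has ≤9
   supergenes, breakpoint-guided candidates (operand boundaries and
   insertion points restricted to current breakpoints, target-guided tdrl
   splits) with a 4000-state beam above that. Minimum-cost scenarios are
   collected up to a cap of 50 and ordered by event-kind priority
   i < t < iT < tdrl, then lexicographic operands; an empty result is an
   explicit exceeds-bound answer, never a silent failure.

The exhaustive `bfs_oracle` — plain breadth-first enumeration of raw
event applications, no reduction, no detector — is kept as an independent
correctness reference for small instances (≤9 genes or ≤2 events).

Orders with duplicated genes are excluded from inference (mask a copy to
proceed); incomplete orders are usable for statistics and block display
but are pruned from reconstruction.

## Ancestral reconstruction

Internal-node orders are found by candidate-set small parsimony: each
internal node's candidates are its subtree's tip orders, the
intermediates of pairwise minimum scenarios between those tips, and any
user-supplied hypotheses (published ancestral arrangements slot in here).
The minimum-total-cost assignment over the candidate sets is computed
exactly by dynamic programming over the tree (equivalent to exhaustive
combination without the product blow-up). Branch costs are the
lexicographic pair (event count bounded at `pair_cost_events`, saturating
above; signed adjacency breakpoints as a cheap finer-grained
tie-separator), so assignments tied on both components are genuine
ambiguities. Final branch event lists are re-inferred at the full event
bound and replay-checked.

A structural limit is worth stating plainly: a lone invertible event on
the root edge cannot be polarised by parsimony — placing it on either
stem costs the same. The reconstruction therefore reports every
minimum-cost root arrangement (primary pick plus `ties`) instead of
pretending to resolve it; on simulated 8-tip histories the tie sets are
small (≤3). Polarity in real analyses comes from the rooting (the
outgroup drawn to the root) and from the directionality of tdrl, which
does break many such ties. Synapomorphy reports list the events on a
clade's stem branch with the derived placements they create; a
non-monophyletic tip set is an error.

## Synthetic studies

The generator is the package's ground truth and emulates the study
system:

- **Histories.** A random rooted binary topology (or a user newick);
  per-branch events drawn with probability 0.3 per slot (one slot by
  default — at most one event per branch), kinds weighted
  t 0.40 / i 0.25 / tdrl 0.25 / iT 0.10, matching the observed
  preponderance of tRNA transpositions and tdrls with occasional
  inversions; segment lengths geometric with mean 2 genes. Events are
  drawn in canonical form (tdrl boundary genes assigned so the event's
  mismatch window is the whole segment) and never cross the cox1 anchor.
  Replaying the recorded events from the root reproduces every tip
  exactly.
- **Genomes.** Genes are laid down in order with realistic per-gene
  lengths (cox1 ≈ 1.5 kb … atp8 ≈ 160 bp, rRNAs 0.8/1.1 kb, tRNAs
  55–75 bp), giving ~15–17 kb totals. Default composition targets: AT
  72%, AT-skew −0.10, GC-skew +0.20 on the plus strand (minus-strand
  genes are drawn with complement-swapped probabilities). PCGs are built
  codon-wise from stop-free sense codons whose sampling distribution is
  bisection-tuned so the realised AT% lands within ±2 points of target
  despite the exclusion of the AT-rich stop codons; starts and stops are
  drawn from the empirically common tallies, and truncated stops are laid
  down only where a tRNA abuts at 0 bp. tRNAs carry generated cloverleaf
  dot-bracket strings (D-armless for S1/S2). NCRs are inserted at
  junctions not adjacent to rRNAs (so rRNA extension stays an identity at
  zero noise); the control region (231 bp, AT-rich) sits at a strand
  transition and carries the planted tandem array — by default 8 copies
  of a 19 bp unit — with guard bases so the array cannot extend by
  accident.
- **Annotator views.** Per source, features are dropped, boundary-
  jittered, or spuriously added at configurable rates; structure strings
  accompany true tRNA calls except when omitted. At zero noise the
  curation protocol recovers the true features exactly — the end-to-end
  identity the test suite pins.

What the generator does not emulate: sequence evolution along the tree
(sequences are i.i.d. per genome — the downstream inferences consume gene
orders, not alignments), realistic gene overlaps (generated genomes are
overlap-free; overlap statistics are exercised on hand-built fixtures),
secondary-structure thermodynamics, and within-genome rate heterogeneity.
Passing tests therefore demonstrate correctness of the algorithms under
the stated generative model, not robustness to every artefact of real
annotation.

## Validation studies and problem sizes

The seeded studies behind `scripts/acceptance.py` and the acceptance
tests use: 200 random instances of 5–8 genes with ≤2 planted events for
the oracle comparison (the exhaustive oracle is what bounds the instance
size); 100 trials per event kind for single-event recovery on full
37-gene orders; 100 replicates of 8-tip histories for root recovery; one
4-tip fully-simulated study for the conservation and motif checks; and
the bundled reference arrangements for the deterministic block-scenario
counts. Root recovery is scored against the reported minimum-cost root
set (primary + ties), for the polarisation reason above; the stricter
primary-pick rate is reported alongside.

## Known limitations

- Events spanning the linearisation anchor are not searched; scenarios
  that genuinely require moving cox1 would be missed (none of the
  modelled rearrangements do).
- The deeper-than-single-event search is exhaustive only on small reduced
  alphabets; above that the breakpoint-guided beam is a heuristic —
  scenario costs are upper bounds there, co-optimal enumeration may be
  incomplete, and the oracle equivalence guarantee covers the exhaustive
  regime.
- Gene orders with unequal content or retained duplications are out of
  scope for scenario inference by design.
- The ancestral candidate sets contain pairwise-scenario intermediates,
  not full single-event neighbourhoods; a true ancestor lying on no
  minimum path between any tip pair can be missed (rare at the simulated
  event densities, and user candidates close the gap when a hypothesis
  exists).
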