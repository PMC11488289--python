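# mitorder

Comparative analysis of mitochondrial genome architecture, built for the
kind of study that sequences a handful of ~15–17 kb circular mitogenomes in
a neglected invertebrate clade (here: solenogaster molluscs and their
aculiferan relatives) and asks what the genomes look like and how their
gene arrangements evolved.

The package covers the full desk workflow downstream of assembly:

- **Annotation curation** (`mitorder.annotate`) — reconcile the feature
  calls of several annotators. A tRNA is accepted when two sources agree
  (same label, same strand, ≥1 bp overlap) or when a single source's
  predicted secondary structure shows at least an acceptor stem and an
  anticodon arm (D-armless tRNAs such as the serine isoacceptors are
  real). Protein-coding genes are re-edited to start at the first start
  codon (ATG/ATA/ATT/TTG/GTG, invertebrate mitochondrial code) and to end
  at the first in-frame stop — or at a truncated `T(AA)`/`TA(A)` completed
  by polyadenylation when a validated tRNA follows within 2 bp. rRNAs are
  extended outward until they abut their neighbours.
- **Descriptive statistics** (`mitorder.seqstats`) — base composition,
  strand skews (AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C)), codon usage
  and RSCU under translation table 5, start/stop tallies, codon-position
  AT%, the non-coding-region (NCR) inventory on the circular coordinate,
  gene overlaps, and exact tandem-repeat motif arrays in NCRs (the usual
  control-region / origin-of-replication signature).
- **Gene orders** (`mitorder.gene_order`) — circular signed gene orders
  over the canonical 37-gene set, normalisation (cox1 first, forward),
  breakpoint and common-interval comparison, conserved-block extraction,
  tRNA cluster lengths.
- **Rearrangement scenarios** (`mitorder.rearrange`) — minimum-event
  scenarios between two orders under the event repertoire inversion (i),
  transposition (t), inverse transposition (iT) and
  tandem-duplication–random-loss (tdrl), with all co-optimal scenarios
  reported and an exhaustive oracle for verification.
- **Ancestral reconstruction** (`mitorder.ancestral`) — candidate-set
  small parsimony on a fixed rooted tree: internal-node gene orders,
  per-branch event lists, and synapomorphy reports for named clades.
- **Synthetic studies** (`mitorder.synthetic`) — a fully seeded generator
  producing genomes with the conserved three-block architecture, known
  rearrangement histories, AT-biased composition with configurable skews,
  planted control-region motif arrays, and noisy multi-annotator views —
  the ground truth every stage is tested against.

## Worked example

`examples/03_rearrangement_scenarios.py` recomputes the rearrangements
separating the aculiferan ancestral gene order from the solenogaster
ancestral order, per conserved block:

```
blocks 1+2: minimum 3 events (50 co-optimal scenarios)
  1. t: D -> after atp8
  2. tdrl: -F,-nad5,-H,-nad4,-nad4L,T,-S2,-cob,-nad6,P (keep-first: T,P)
  3. t: -L1 -> after -G

block 3: minimum 2 events (50 co-optimal scenarios)
  1. t: A,R -> after cox3
  2. tdrl: cox3,A,R,K,N,I (keep-first: R,K,I)
```

Read: relative to the aculiferan arrangement, the solenogaster stem line
moved trnD between atp8 and atp6 (a transposition), left trnT and trnP
adjacent to atp6 through one tandem-duplication–random-loss over the
block-1/block-2 junction, and moved trnL1 next to trnE — completing the
MCYWQGL1E tRNA block. Two further events rearrange the KARNI tRNA cluster
of block 3. Each line is one event; `keep-first` names the genes retained
from the first tandem copy in a tdrl; every scenario is replay-checked
(applying the events to the source reproduces the target), and co-optimal
alternatives are enumerated rather than silently discarded.

The other examples demonstrate per-genome statistics, curation of noisy
annotator calls, ancestral reconstruction on simulated histories, and
conserved-block analysis. A thin command-line interface wires the same
functions into shell pipelines (`mitorder simulate | curate | stats |
order | compare | tree | report`); every run writes a manifest recording
inputs, parameters and seed.

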