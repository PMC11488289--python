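"""Descriptive statistics for one mitogenome.

Simulates a single annotated ~15 kb genome, then computes the statistics a
comparative study tabulates per genome: base composition and strand skews,
codon usage (start/stop tallies, RSCU), the non-coding-region inventory,
gene overlaps, and the control-region tandem motif.
"""

from mitorder import (
    SimConfig,
    at_richest_ncr,
    codon_usage,
    composition,
    find_ncrs,
    find_overlaps,
    find_tandem_motifs,
    simulate_genome,
    simulate_orders,
    summarize_ncrs,
)

cfg = SimConfig(seed=11, n_tips=2)
truth = simulate_orders(cfg)
tip = sorted(truth.tip_orders)[0]
genome, features, motif = simulate_genome(truth.tip_orders[tip], cfg, cfg.rng())
genes = [f for f in features if f.ftype != "NCR"]

comp = composition(genome.sequence)
print(f"genome {genome.id}: {genome.length} bp")
print(f"  AT% {comp.at_percent:.1f}  GC% {comp.gc_percent:.1f}  "
      f"AT-skew {comp.at_skew:.4f}  GC-skew {comp.gc_skew:.4f}")
# negative AT-skew with positive GC-skew is the usual pattern on the
# deposited plus strand of these genomes

usage = codon_usage(genome, [f for f in genes if f.ftype == "PCG"])
print(f"  start codons: {dict(usage.start_tally)}")
print(f"  stop codons:  {dict(usage.stop_tally)}  "
      "(T(AA)/TA(A) are completed by polyadenylation)")
print(f"  codon-position AT%: " +
      ", ".join(f"{x:.1f}" for x in usage.position_at) +
      "  (3rd position is typically the most AT-rich)")

ncrs = find_ncrs(genome, genes)
print(f"  NCRs: {summarize_ncrs(ncrs, genome.length)}")
best = at_richest_ncr(ncrs)
print(f"  AT-richest NCR: {best.length} bp at {best.start} "
      f"({best.at_percent:.1f}% AT) between {best.flank_upstream} and "
      f"{best.flank_downstream} — the control-region candidate")
for m in find_tandem_motifs(genome.span_seq(best.start, best.end)):
    print(f"    tandem array: {m.copies}x {m.unit} ({m.unit_length} bp unit)")

overlaps, total = find_overlaps(genome, genes)
print(f"  gene overlaps: {len(overlaps)} totalling {total} bp")
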