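"""Seeded end-to-end validation studies.

Each function runs one part of the pipeline from scratch under a seed and
returns the measured quantities; they back both the acceptance test suite
and ``scripts/acceptance.py``.  Sub-seeds are spawned deterministically
from the master seed, so one integer reproduces every study.
"""

from __future__ import annotations

import numpy as np

from . import vocab
from .ancestral import node_key, reconstruct
from .annotate import curate
from .gene_order import (
    GeneOrder,
    largest_trna_cluster,
    normalize,
    reference_orders,
)
from .model import revcomp
from .rearrange import apply_event, bfs_oracle, infer_scenario
from .seqstats import (
    composition,
    codon_usage,
    find_ncrs,
    find_tandem_motifs,
    synonymous_families,
)
from .synthetic import SimConfig, random_event, simulate_orders, simulate_study


def _subseed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# Scenario inference vs the exhaustive oracle

def oracle_equivalence_study(seed: int, n_instances: int = 200) -> dict:
    """Random small instances (<= 8 genes, <= 2 planted events): the bounded
    production search must match the exhaustive oracle's minimum cost, and
    every returned scenario must replay source -> target."""
    rng = np.random.default_rng(_subseed(seed, 1))
    agree = replayed = scenarios = 0
    for _ in range(n_instances):
        n = int(rng.integers(5, 9))
        signs = rng.choice([1, -1], size=n)
        genes = (1,) + tuple(int(s) * (i + 1)
                             for i, s in zip(range(1, n), signs[1:]))
        src = GeneOrder("s", genes)
        cur = src
        for _ in range(int(rng.integers(0, 3))):
            cur = apply_event(cur, random_event(cur.genes, rng))
        res = infer_scenario(src, cur, max_events=2)
        oracle = bfs_oracle(src, cur, max_events=2)
        if res.cost == oracle:
            agree += 1
        for sc in res.scenarios:
            scenarios += 1
            if sc.replays():
                replayed += 1
    return {
        "n": n_instances,
        "cost_agreement": agree,
        "scenarios": scenarios,
        "replayed": replayed,
    }


# ---------------------------------------------------------------------------
# Single planted events on full 37-gene orders

def single_event_recovery_study(seed: int, trials_per_kind: int = 100) -> dict:
    """Plant one i/t/iT/tdrl on the 37-gene reference order; inference must
    return cost 1 with the planted kind and operand span among the
    co-optimal scenarios."""
    root = reference_orders()["aculifera_ancestor"]
    rng = np.random.default_rng(_subseed(seed, 2))
    recovered = {}
    for kind in ("i", "t", "iT", "tdrl"):
        ok = 0
        for _ in range(trials_per_kind):
            ev = random_event(root.genes, rng, kind_weights={kind: 1.0})
            target = apply_event(root, ev)
            res = infer_scenario(root, target, max_events=2)
            if res.cost != 1:
                continue
            span = frozenset(t.lstrip("-") for t in ev.genes)
            if any(
                e.kind == kind
                and frozenset(t.lstrip("-") for t in e.genes) == span
                for sc in res.scenarios for e in sc.events
            ):
                ok += 1
        recovered[kind] = ok
    recovered["n_per_kind"] = trials_per_kind
    return recovered


# ---------------------------------------------------------------------------
# Ancestral root recovery

def ancestral_recovery_study(
    seed: int, n_reps: int = 100, n_tips: int = 8
) -> dict:
    """Simulated histories (<= 1 event/branch): how often the true root is
    the primary reconstructed order, and how often it is in the reported
    minimum-cost root set (primary + ties)."""
    primary = in_set = 0
    tie_total = 0
    for rep in range(n_reps):
        cfg = SimConfig(seed=_subseed(seed, 100 + rep), n_tips=n_tips)
        truth = simulate_orders(cfg)
        lt = reconstruct(truth.tree, truth.tip_orders)
        rkey = node_key(truth.tree.seed_node)
        want = str(normalize(truth.root_order))
        got = str(lt.orders[rkey])
        if got == want:
            primary += 1
            in_set += 1
        elif want in lt.ties:
            in_set += 1
        tie_total += len(lt.ties)
    return {
        "n": n_reps,
        "primary": primary,
        "in_min_cost_set": in_set,
        "mean_ties": tie_total / n_reps,
    }


# ---------------------------------------------------------------------------
# Conservation laws and skew symmetry

def conservation_study(seed: int, n_tips: int = 4) -> dict:
    """Coverage conservation, RSCU family sums and skew antisymmetry on a
    fully simulated study plus random sequences."""
    truth = simulate_study(SimConfig(seed=_subseed(seed, 3), n_tips=n_tips))
    coverage_violations = 0
    rscu_err = 0.0
    fams = synonymous_families()
    for tip, genome in truth.genomes.items():
        feats = [f for f in truth.features[tip] if f.ftype != "NCR"]
        ncrs = find_ncrs(genome, feats)
        covered = sum(f.length for f in feats)
        if covered + sum(r.length for r in ncrs) != genome.length:
            coverage_violations += 1
        calls = [c for src in truth.views[tip].values() for c in src]
        cur = curate(genome, calls)
        pcgs = [f for f in cur.accepted if f.ftype == "PCG"]
        usage = codon_usage(genome, pcgs, cur.codon_records)
        for aa, codons in fams.items():
            total = sum(usage.counts.get(c, 0) for c in codons)
            if total:
                rscu_err = max(rscu_err, abs(
                    sum(usage.rscu[c] for c in codons) - len(codons)
                ))
    rng = np.random.default_rng(_subseed(seed, 4))
    skew_err = 0.0
    seqs = [g.sequence for g in truth.genomes.values()]
    seqs += ["".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 500))))
             for _ in range(20)]
    for s in seqs:
        a, b = composition(s), composition(revcomp(s))
        skew_err = max(skew_err, abs(a.at_skew + b.at_skew),
                       abs(a.gc_skew + b.gc_skew))
        if not (-1.0 <= a.at_skew <= 1.0 and -1.0 <= a.gc_skew <= 1.0):
            skew_err = max(skew_err, 2.0)
    return {
        "genomes": len(truth.genomes),
        "coverage_violations": coverage_violations,
        "rscu_family_sum_max_abs_error": rscu_err,
        "skew_negation_max_abs_error": skew_err,
    }


# ---------------------------------------------------------------------------
# Planted control-region motifs

def motif_recovery_study(seed: int, n_tips: int = 4) -> dict:
    """The generator plants the 19 bp control-region motif array; the motif
    scanner must recover exact unit, copy number and coordinates."""
    truth = simulate_study(SimConfig(seed=_subseed(seed, 5), n_tips=n_tips))
    exact = 0
    unit_len = copies = 0
    for tip, motif in truth.motifs.items():
        genome = truth.genomes[tip]
        feats = [f for f in truth.features[tip] if f.ftype != "NCR"]
        found = []
        for r in find_ncrs(genome, feats):
            for m in find_tandem_motifs(genome.span_seq(r.start, r.end)):
                found.append((r.start + m.start, m.unit, m.copies))
        if (motif.start, motif.unit, motif.copies) in found:
            exact += 1
            unit_len, copies = len(motif.unit), motif.copies
    return {
        "planted": len(truth.motifs),
        "recovered_exactly": exact,
        "unit_length": unit_len,
        "copies": copies,
    }


# ---------------------------------------------------------------------------
# Quantities recomputable from the printed ancestral arrangements

BLOCK3 = frozenset({"cox3", "K", "A", "R", "N", "I", "nad3", "S1", "nad2"})


def _restrict(order: GeneOrder, keep: frozenset[str], oid: str) -> GeneOrder:
    genes = tuple(g for g in order.genes if vocab.ID_GENE[abs(g)] in keep)
    return GeneOrder(oid, genes, complete=False)


def printed_order_quantities() -> dict:
    """Deterministic gene-order numbers from the bundled reference
    arrangements: per-block stem scenario costs and tRNA cluster sizes."""
    refs = reference_orders()
    acu = refs["aculifera_ancestor"]
    sol = refs["solenogastres_ancestor"]
    cau = refs["caudofoveata_ancestor"]
    wir = refs["wirenia_argentea"]
    all_labels = frozenset(vocab.ID_GENE[abs(g)] for g in acu.genes)

    def block_cost(src, tgt, keep):
        res = infer_scenario(_restrict(src, keep, "a"),
                             _restrict(tgt, keep, "b"), max_events=4)
        return res.cost if res.cost is not None else -1

    sol_12 = block_cost(acu, sol, all_labels - BLOCK3)
    sol_3 = block_cost(acu, sol, BLOCK3 | {"cox1"})
    cau_2 = block_cost(acu, cau, all_labels - BLOCK3 - {"E"})
    cau_3 = block_cost(acu, cau, BLOCK3 | {"cox1", "E"})

    sol_n = normalize(sol)
    labels = [x.lstrip("-") for x in sol_n.labels]
    i = labels.index("M")
    cluster = labels[i : i + 8]
    return {
        "solenogaster_stem_block12_events": sol_12,
        "solenogaster_stem_block3_events": sol_3,
        "solenogaster_stem_total_events": sol_12 + sol_3,
        "caudofoveate_stem_block2_events": cau_2,
        "caudofoveate_stem_block3_events": cau_3,
        "wirenia_largest_trna_cluster": largest_trna_cluster(wir),
        "mcywqgl1e_cluster_length": len(cluster)
        if cluster == ["M", "C", "Y", "W", "Q", "G", "L1", "E"] else 0,
    }
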