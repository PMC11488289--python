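"""Ground-truthed synthetic mitogenomes, histories and annotator views.

The generator emulates the study system: circular ~15–17 kb genomes carrying
the canonical 37-gene metazoan set in the conserved three-block architecture
(forward / reverse / forward), rearrangement histories along a rooted tree
with known event types, AT-biased composition with configurable strand
skews, intergenic NCRs with a planted control-region tandem-motif array,
and noisy multi-annotator feature calls.

Everything is driven by one integer seed; replaying the recorded branch
events from the root order reproduces every tip order exactly, and at zero
annotator noise the curation pipeline recovers the true features exactly.

Orders evolve; sequences are drawn i.i.d. per genome (no substitution model
along the tree — gene-order inference, not sequence inference, is what the
downstream analyses test).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio.Data import CodonTable

from . import vocab
from .gene_order import GeneOrder, reference_orders
from .model import AnnotatedGenome, Feature, revcomp
from .rearrange import Event, apply_event
from .seqstats import INVERTEBRATE_MITO_TABLE

#: typical coding lengths (bp) of the mitochondrial PCGs and rRNAs
TYPICAL_LENGTH = {
    "cox1": 1533, "cox2": 687, "cox3": 780, "cob": 1140,
    "nad1": 933, "nad2": 987, "nad3": 354, "nad4": 1380, "nad4L": 297,
    "nad5": 1716, "nad6": 480, "atp6": 678, "atp8": 159,
    "rrnS": 800, "rrnL": 1100,
}

START_CODON_WEIGHTS = {"ATG": 0.53, "ATA": 0.30, "ATT": 0.12,
                       "TTG": 0.025, "GTG": 0.025}
FULL_STOP_WEIGHTS = {"TAA": 0.77, "TAG": 0.23}

#: D-armless tRNAs (both serine isoacceptors lack the D-arm in these genomes)
D_ARMLESS = {"S1", "S2"}


@dataclass
class SimConfig:
    """Generator parameters; the defaults are the study conditions."""

    seed: int = 0
    # history
    n_tips: int = 8
    tree_newick: str | None = None
    root_order: GeneOrder | None = None  # default: aculiferan reference
    branch_event_prob: float = 0.3
    max_events_per_branch: int = 1
    event_kind_weights: Mapping[str, float] = field(
        default_factory=lambda: {"t": 0.40, "i": 0.25, "tdrl": 0.25, "iT": 0.10}
    )
    segment_mean_len: float = 2.0  # geometric mean segment length (genes)
    # sequence
    at_percent: float = 72.0
    at_skew: float = -0.10
    gc_skew: float = 0.20
    pcg_length_jitter: int = 30  # +/- bp, kept a codon multiple
    trna_len: tuple[int, int] = (55, 75)
    rrna_jitter: int = 100
    truncated_stop_prob: float = 0.25
    # NCRs
    n_ncrs: int = 12
    ncr_len: tuple[int, int] = (1, 60)
    control_region_len: int = 231
    motif_unit: str = "CTATTATATATATATATTA"
    motif_copies: int = 8
    # annotator noise
    n_sources: int = 2
    source_names: tuple[str, ...] = ("mitos", "arwen")
    drop_prob: float = 0.0
    jitter_bp: int = 0
    false_call_prob: float = 0.0
    structure_omission_prob: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.branch_event_prob, self.drop_prob,
                  self.false_call_prob, self.structure_omission_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.pcg_length_jitter % 3:
            raise ValueError("pcg_length_jitter must be a codon multiple")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PlantedMotif:
    unit: str
    copies: int
    start: int  # genome coordinate


@dataclass
class GroundTruth:
    root_order: GeneOrder
    tree: dendropy.Tree
    newick: str
    tip_orders: dict[str, GeneOrder]
    branch_events: dict[str, list[Event]]  # child node key -> events
    genomes: dict[str, AnnotatedGenome] = field(default_factory=dict)
    features: dict[str, list[Feature]] = field(default_factory=dict)
    motifs: dict[str, PlantedMotif] = field(default_factory=dict)
    views: dict[str, dict[str, list[Feature]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Histories

def _random_tree(n_tips: int, rng: np.random.Generator) -> str:
    """Random rooted binary topology over tips t1..tn (newick)."""
    nodes = [f"t{i+1}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b})"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0] + ";"


def random_event(
    genes: tuple[int, ...],
    rng: np.random.Generator,
    kind_weights: Mapping[str, float] | None = None,
    mean_len: float = 2.0,
    max_tries: int = 100,
) -> Event:
    """Draw one applicable event in canonical form.

    Segments never include position 0 (the linearisation anchor, cox1), so
    events stay within the circle's gene blocks.  tdrl partitions are drawn
    canonical (first segment gene in the keep-second set, last in keep-first)
    so the event's minimal mismatch window is the full segment.
    """
    weights = dict(kind_weights or {"t": 0.4, "i": 0.25, "tdrl": 0.25, "iT": 0.1})
    kinds = sorted(weights)
    probs = np.array([weights[k] for k in kinds], dtype=float)
    probs /= probs.sum()
    n = len(genes)
    from .gene_order import signed_label  # local import to avoid cycle noise

    for _ in range(max_tries):
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        min_len = 2 if kind == "tdrl" else 1
        L = min_len + int(rng.geometric(1.0 / mean_len)) - 1
        L = min(L, n - 2)
        if L < min_len:
            continue
        i = int(rng.integers(1, n - L + 1))
        seg = genes[i : i + L]
        seg_labels = tuple(signed_label(g) for g in seg)
        if kind == "i":
            ev = Event("i", seg_labels)
        elif kind in ("t", "iT"):
            dest = int(rng.integers(1, n - L + 1))
            if kind == "t" and dest == i:
                continue  # identity transposition
            if kind == "iT" and dest == i:
                continue  # in-place iT is an inversion
            rest = genes[:i] + genes[i + L :]
            after = signed_label(rest[dest - 1])
            ev = Event(kind, seg_labels, after=after)
        else:  # tdrl
            if L < 2:
                continue
            mask = rng.random(L) < 0.5
            mask[0] = False   # first gene goes to the keep-second set
            mask[-1] = True   # last gene to the keep-first set
            if mask.all() or not mask.any():
                continue
            kf = tuple(signed_label(g) for g, m in zip(seg, mask) if m)
            ev = Event("tdrl", seg_labels, keep_first=kf)
        probe = GeneOrder("probe", genes)
        if apply_event(probe, ev).genes != genes:
            return ev
    raise RuntimeError("could not draw an applicable event (order too small?)")


def simulate_orders(
    config: SimConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Evolve gene orders root -> tips along a (given or random) tree."""
    rng = rng if rng is not None else config.rng()
    root = config.root_order or reference_orders()["aculifera_ancestor"]
    newick = config.tree_newick or _random_tree(config.n_tips, rng)
    tree = dendropy.Tree.get(
        data=newick, schema="newick",
        preserve_underscores=True, suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True

    from .ancestral import node_key

    orders: dict[str, GeneOrder] = {}
    branch_events: dict[str, list[Event]] = {}
    tip_orders: dict[str, GeneOrder] = {}
    for node in tree.preorder_node_iter():
        key = node_key(node)
        if node.parent_node is None:
            orders[key] = replace(root, id=key)
            continue
        parent = orders[node_key(node.parent_node)]
        current = parent
        events: list[Event] = []
        for _ in range(config.max_events_per_branch):
            if rng.random() < config.branch_event_prob:
                ev = random_event(
                    current.genes, rng,
                    config.event_kind_weights, config.segment_mean_len,
                )
                current = apply_event(current, ev)
                events.append(ev)
        orders[key] = replace(current, id=key)
        branch_events[key] = events
        if node.is_leaf():
            tip_orders[node.taxon.label] = orders[key]
    return GroundTruth(
        root_order=root, tree=tree, newick=newick,
        tip_orders=tip_orders, branch_events=branch_events,
    )


# ---------------------------------------------------------------------------
# Sequences

def _base_probs(at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """P(A), P(C), P(G), P(T) on the plus strand."""
    at /= 100.0 if at > 1.0 else 1.0
    gc = 1.0 - at
    return np.array([
        at * (1 + at_skew) / 2,
        gc * (1 - gc_skew) / 2,
        gc * (1 + gc_skew) / 2,
        at * (1 - at_skew) / 2,
    ])


_BASES = np.array(list("ACGT"))


def _random_seq(n: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=probs)])


def _sense_codons(table_id: int = INVERTEBRATE_MITO_TABLE) -> list[str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return sorted(table.forward_table)


def _codon_probs(probs: np.ndarray, codons: Sequence[str]) -> np.ndarray:
    idx = {b: i for i, b in enumerate("ACGT")}
    w = np.array([probs[idx[c[0]]] * probs[idx[c[1]]] * probs[idx[c[2]]]
                  for c in codons])
    return w / w.sum()


def _codon_at_fraction(codons: Sequence[str], p: np.ndarray) -> float:
    return float(sum(
        pi * sum(b in "AT" for b in c) / 3 for pi, c in zip(p, codons)
    ))


def _tuned_codon_probs(
    base: np.ndarray, codons: Sequence[str], target_at: float
) -> np.ndarray:
    """Bisection on the AT mass so codon sampling hits the target AT%.

    Excluding the stop codons removes AT-rich mass; a scalar reweighting of
    the A/T base probabilities compensates.
    """
    lo, hi = 0.5, 2.0
    for _ in range(25):
        lam = (lo + hi) / 2
        probs = base.copy()
        probs[[0, 3]] *= lam
        probs /= probs.sum()
        p = _codon_probs(probs, codons)
        if _codon_at_fraction(codons, p) < target_at:
            lo = lam
        else:
            hi = lam
    return p


def _pcg_length(label: str, jitter: int, rng: np.random.Generator) -> int:
    base = TYPICAL_LENGTH[label]
    return base + 3 * int(rng.integers(-jitter // 3, jitter // 3 + 1))


def _weighted_choice(d: Mapping[str, float], rng: np.random.Generator) -> str:
    keys = sorted(d)
    p = np.array([d[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def make_pcg_seq(
    length: int, codon_p: np.ndarray, codons: Sequence[str],
    rng: np.random.Generator, stop: str = "TAA",
) -> str:
    """A coding-strand PCG: start codon, stop-free body, terminal stop.

    ``stop`` may be truncated ("T" or "TA"); the returned length is then
    ``length - 2`` or ``length - 1``.
    """
    n_body = length // 3 - 2
    start = _weighted_choice(START_CODON_WEIGHTS, rng)
    body_idx = rng.choice(len(codons), size=n_body, p=codon_p)
    body = "".join(codons[i] for i in body_idx)
    return start + body + stop


def cloverleaf(length: int, d_arm: bool = True) -> str:
    """A dot-bracket cloverleaf of exactly ``length`` characters.

    Acceptor stem 7 bp; D stem 3 bp, anticodon stem 5 bp, T stem 4 bp; loop
    sizes shrink (down to 3) to fit short tRNAs and a 3' discriminator pads
    to the requested length.  D-armless layouts model the serine tRNAs.
    """
    for d_loop, t_loop, ac_loop in ((8, 5, 7), (5, 4, 7), (3, 3, 7), (3, 3, 5)):
        parts = ["(" * 7, "."]
        if d_arm:
            parts += ["(" * 3, "." * d_loop, ")" * 3, "."]
        parts += ["(" * 5, "." * ac_loop, ")" * 5, "."]
        parts += ["(" * 4, "." * t_loop, ")" * 4]
        parts += [")" * 7]
        s = "".join(parts)
        if len(s) <= length:
            return s + "." * (length - len(s))
    raise ValueError(f"tRNA length {length} too short for a cloverleaf")


# ---------------------------------------------------------------------------
# Genome assembly

def simulate_genome(
    order: GeneOrder, config: SimConfig,
    rng: np.random.Generator | None = None,
    genome_id: str | None = None,
) -> tuple[AnnotatedGenome, list[Feature], PlantedMotif | None]:
    """Realise one annotated genome for a gene order.

    Returns the genome, its true features, and the planted control-region
    motif.  Layout rules keep the curation protocol an exact identity at
    zero noise: rRNAs abut their neighbours (no gap on either side), PCGs
    start at their first start codon and stop at their first stop, and a
    truncated stop is laid down only where a tRNA follows within 0 bp.
    """
    rng = rng if rng is not None else config.rng()
    plus = _base_probs(config.at_percent, config.at_skew, config.gc_skew)
    minus = plus[::-1]  # complement-swapped probabilities
    codons = _sense_codons()
    target_at = config.at_percent / 100.0
    codon_p_plus = _tuned_codon_probs(plus, codons, target_at)
    codon_p_minus = _tuned_codon_probs(minus, codons, target_at)

    labels = [vocab.ID_GENE[abs(g)] for g in order.genes]
    strands = ["+" if g > 0 else "-" for g in order.genes]
    ftypes = [vocab.feature_type(lb) for lb in labels]
    n = len(labels)

    # decide truncated stops: a PCG whose coding-strand downstream neighbour
    # is a tRNA may end in T/TA with a 0 bp gap to that tRNA
    truncated: dict[int, str] = {}
    for k in range(n):
        if ftypes[k] != "PCG":
            continue
        nbr = (k + 1) % n if strands[k] == "+" else (k - 1) % n
        if ftypes[nbr] == "tRNA" and rng.random() < config.truncated_stop_prob:
            truncated[k] = "T" if rng.random() < 0.85 else "TA"

    # gene sequences on their coding strands
    gene_seqs: list[str] = []
    structures: list[str | None] = []
    for k in range(n):
        label, ftype = labels[k], ftypes[k]
        cp = codon_p_plus if strands[k] == "+" else codon_p_minus
        bp = plus if strands[k] == "+" else minus
        if ftype == "PCG":
            length = _pcg_length(label, config.pcg_length_jitter, rng)
            stop = truncated.get(k) or _weighted_choice(FULL_STOP_WEIGHTS, rng)
            gene_seqs.append(make_pcg_seq(length, cp, codons, rng, stop))
            structures.append(None)
        elif ftype == "rRNA":
            length = TYPICAL_LENGTH[label] + int(
                rng.integers(-config.rrna_jitter, config.rrna_jitter + 1)
            )
            gene_seqs.append(_random_seq(length, bp, rng))
            structures.append(None)
        else:
            length = int(rng.integers(config.trna_len[0], config.trna_len[1] + 1))
            gene_seqs.append(_random_seq(length, bp, rng))
            structures.append(cloverleaf(length, d_arm=label not in D_ARMLESS))

    # NCR placement: junction k sits between gene k and gene k+1 (mod n);
    # never adjacent to an rRNA, never where a truncated stop needs 0 bp
    forbidden = set()
    for k in range(n):
        if ftypes[k] == "rRNA":
            forbidden.add(k)
            forbidden.add((k - 1) % n)
    for k, tail in truncated.items():
        forbidden.add(k if strands[k] == "+" else (k - 1) % n)
    eligible = [k for k in range(n) if k not in forbidden]
    # control region at a strand transition (the usual origin location)
    transitions = [k for k in eligible if strands[k] != strands[(k + 1) % n]]
    cr_junction = int(rng.choice(transitions if transitions else eligible))
    others = [k for k in eligible if k != cr_junction]
    n_plain = min(max(config.n_ncrs - 1, 0), len(others))
    plain = set(
        int(x) for x in rng.choice(len(others), size=n_plain, replace=False)
    )
    ncr_at: dict[int, str] = {}

    at_rich = _base_probs(86.0, 0.0, 0.0)
    motif_block = config.motif_unit * config.motif_copies
    if config.control_region_len and config.motif_copies:
        pad = max(config.control_region_len - len(motif_block) - 2, 0)
        left = int(rng.integers(0, pad + 1)) if pad else 0
        cr_seq = (
            _random_seq(left, at_rich, rng) + "G" + motif_block + "G"
            + _random_seq(pad - left, at_rich, rng)
        )
        motif_off = left + 1
        ncr_at[cr_junction] = cr_seq
    else:
        motif_off = None
    for idx, k in enumerate(others):
        if idx in plain:
            length = int(rng.integers(config.ncr_len[0], config.ncr_len[1] + 1))
            ncr_at[k] = _random_seq(length, plus, rng)

    # assembly
    seq_parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    motif_truth: PlantedMotif | None = None
    for k in range(n):
        s = gene_seqs[k]
        span = revcomp(s) if strands[k] == "-" else s
        features.append(Feature(
            label=labels[k], ftype=ftypes[k], strand=strands[k],
            start=pos, end=pos + len(span), source="truth",
            structure=structures[k],
        ))
        seq_parts.append(span)
        pos += len(span)
        if k in ncr_at:
            ncr_seq = ncr_at[k]
            features.append(Feature(
                label=f"NCR@{pos}", ftype="NCR", strand="+",
                start=pos, end=pos + len(ncr_seq), source="truth",
            ))
            if k == cr_junction and motif_off is not None:
                motif_truth = PlantedMotif(
                    unit=config.motif_unit, copies=config.motif_copies,
                    start=pos + motif_off,
                )
            seq_parts.append(ncr_seq)
            pos += len(ncr_seq)

    genome = AnnotatedGenome(
        id=genome_id or order.id, sequence="".join(seq_parts),
        circular=True, features=features,
    )
    return genome, features, motif_truth


# ---------------------------------------------------------------------------
# Annotator views

def emit_annotator_views(
    features: Sequence[Feature],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    genome_length: int | None = None,
) -> dict[str, list[Feature]]:
    """Noisy per-source feature calls for the curation pipeline.

    Per source, gene features are dropped / boundary-jittered / falsely
    added per the configured rates; structure strings ride along on true
    tRNA calls except where omitted.  NCR features are never 'called'.
    """
    rng = rng if rng is not None else config.rng()
    sources = config.source_names[: config.n_sources]
    views: dict[str, list[Feature]] = {}
    genes = [f for f in features if f.ftype in ("PCG", "rRNA", "tRNA")]
    for src in sources:
        calls: list[Feature] = []
        for f in genes:
            if rng.random() < config.drop_prob:
                continue
            start, end = f.start, f.end
            if config.jitter_bp:
                start += int(rng.integers(-config.jitter_bp, config.jitter_bp + 1))
                end += int(rng.integers(-config.jitter_bp, config.jitter_bp + 1))
                start = max(start, 0)
                end = max(end, start + 3)
            structure = f.structure
            if structure is not None and (
                (end - start) != len(structure)
                or rng.random() < config.structure_omission_prob
            ):
                structure = None
            calls.append(replace(f, start=start, end=end, source=src,
                                 structure=structure, flags=()))
        if rng.random() < config.false_call_prob and genome_length:
            label = vocab.TRNAS[int(rng.integers(len(vocab.TRNAS)))]
            start = int(rng.integers(0, genome_length - 70))
            calls.append(Feature(
                label=label, ftype="tRNA",
                strand="+" if rng.random() < 0.5 else "-",
                start=start, end=start + 65, source=src,
            ))
        views[src] = calls
    return views


# ---------------------------------------------------------------------------
# Orchestration

def simulate_study(config: SimConfig) -> GroundTruth:
    """Full simulation: histories, one genome per tip, annotator views."""
    rng = config.rng()
    truth = simulate_orders(config, rng)
    for tip in sorted(truth.tip_orders):
        order = truth.tip_orders[tip]
        genome, feats, motif = simulate_genome(order, config, rng, genome_id=tip)
        truth.genomes[tip] = genome
        truth.features[tip] = feats
        if motif is not None:
            truth.motifs[tip] = motif
        truth.views[tip] = emit_annotator_views(
            feats, config, rng, genome_length=genome.length
        )
    return truth
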