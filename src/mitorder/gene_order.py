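"""Circular signed gene orders: extraction, normalisation, comparison.

A :class:`GeneOrder` is a circular arrangement of signed canonical labels
(sign = strand).  Orders are compared after :func:`normalize` (rotated so
cox1 comes first and reads on the plus strand); no reflection is applied
during comparison, because the two strands are biologically meaningful.

The conserved architecture of these genomes is a three-block layout — a
forward block, a reverse block carrying both rRNAs, and a second forward
block — recovered here via common intervals (gene sets contiguous in every
order) and via strand runs (:func:`three_block_partition`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from . import vocab
from .model import AnnotatedGenome, Feature

SignedGenes = tuple[int, ...]


@dataclass(frozen=True)
class GeneOrder:
    """Circular signed arrangement of canonical gene labels."""

    id: str
    genes: SignedGenes  # signed vocabulary ids, plus-strand positional order
    complete: bool = True
    has_duplication: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty gene order")
        seen = [abs(g) for g in self.genes]
        if len(set(seen)) != len(seen) and not self.has_duplication:
            raise ValueError(f"{self.id}: repeated gene without has_duplication")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(signed_label(g) for g in self.genes)

    def __str__(self) -> str:
        return ",".join(self.labels)


def signed_label(g: int) -> str:
    return ("-" if g < 0 else "") + vocab.ID_GENE[abs(g)]


def parse_signed_label(token: str) -> int:
    token = token.strip()
    sign = -1 if token.startswith("-") else 1
    label = token.lstrip("+-")
    if label not in vocab.GENE_ID:
        canonical = vocab.canonical_label(label)
        if canonical is None:
            raise ValueError(f"unknown gene label {token!r}")
        label = canonical
    return sign * vocab.GENE_ID[label]


def order_from_labels(id: str, labels: Iterable[str], **kw) -> GeneOrder:
    genes = tuple(parse_signed_label(t) for t in labels)
    kw.setdefault("complete", len({abs(g) for g in genes}) == len(vocab.CANONICAL))
    kw.setdefault("has_duplication",
                  len({abs(g) for g in genes}) != len(genes))
    return GeneOrder(id=id, genes=genes, **kw)


# ---------------------------------------------------------------------------
# Extraction from curated features

def from_features(
    genome: AnnotatedGenome | None = None,
    features: Sequence[Feature] | None = None,
    id: str | None = None,
) -> GeneOrder:
    """Extract the circular signed gene order from curated features.

    Genes are ordered by start position; for overlapping pairs the smaller
    start goes first, except that a tRNA overlapping an rRNA always precedes
    it (the coding convention used when a tRNA sits inside an rRNA's 5'
    boundary, as with trnR/rrnS).
    """
    if features is None:
        if genome is None:
            raise ValueError("need a genome or a feature list")
        features = genome.features
    feats = [
        f for f in features
        if f.ftype in ("PCG", "rRNA", "tRNA") and f.label in vocab.GENE_ID
    ]
    feats.sort(key=lambda f: (f.start, f.end, f.label))
    # tRNA-before-rRNA rule for overlapping tRNA/rRNA pairs
    changed = True
    while changed:
        changed = False
        for i in range(len(feats) - 1):
            a, b = feats[i], feats[i + 1]
            if (a.ftype == "rRNA" and b.ftype == "tRNA"
                    and min(a.end, b.end) - max(a.start, b.start) >= 1):
                feats[i], feats[i + 1] = b, a
                changed = True
    genes = tuple(
        (vocab.GENE_ID[f.label] if f.strand == "+" else -vocab.GENE_ID[f.label])
        for f in feats
    )
    labels = [abs(g) for g in genes]
    has_dup = len(set(labels)) != len(labels)
    complete = len(set(labels)) == len(vocab.CANONICAL)
    oid = id or (genome.id if genome is not None else "order")
    return GeneOrder(id=oid, genes=genes, complete=complete,
                     has_duplication=has_dup)


# ---------------------------------------------------------------------------
# Normalisation

def _rotate(genes: SignedGenes, k: int) -> SignedGenes:
    return genes[k:] + genes[:k]


def reverse_flip(genes: SignedGenes) -> SignedGenes:
    """Read the circle from the other strand: reverse order, flip signs."""
    return tuple(-g for g in reversed(genes))


def normalize(order: GeneOrder) -> GeneOrder:
    """Canonical form: rotated so cox1 is first and reads forward.

    If cox1 is absent (incomplete order) the lowest-id gene present anchors
    instead and the order is flagged ``anchored-fallback``.  Idempotent, and
    invariant under rotation and whole-order strand flip.
    """
    anchor = vocab.GENE_ID["cox1"]
    present = {abs(g) for g in order.genes}
    flags = order.flags
    if anchor not in present:
        anchor = min(present)
        if "anchored-fallback" not in flags:
            flags = flags + ("anchored-fallback",)
    genes = order.genes
    idx = next(i for i, g in enumerate(genes) if abs(g) == anchor)
    if genes[idx] < 0:
        genes = reverse_flip(genes)
        idx = next(i for i, g in enumerate(genes) if abs(g) == anchor)
    genes = _rotate(genes, idx)
    return replace(order, genes=genes, flags=flags)


# ---------------------------------------------------------------------------
# Simple descriptors

def largest_trna_cluster(order: GeneOrder) -> int:
    """Length of the maximal circular run of consecutive tRNA genes."""
    is_t = [vocab.is_trna(vocab.ID_GENE[abs(g)]) for g in order.genes]
    if all(is_t):
        return len(is_t)
    doubled = is_t + is_t
    best = run = 0
    for v in doubled:
        run = run + 1 if v else 0
        best = max(best, run)
    return min(best, len(is_t))


def _adjacency_set(genes: SignedGenes) -> set[tuple[int, int]]:
    """Signed circular adjacencies, canonicalised so (x,y) == (-y,-x)."""
    n = len(genes)
    out = set()
    for i in range(n):
        x, y = genes[i], genes[(i + 1) % n]
        out.add(min((x, y), (-y, -x)))
    return out


def adjacency_breakpoints(
    a: GeneOrder, b: GeneOrder
) -> tuple[set[tuple[int, int]], int]:
    """Shared signed circular adjacencies of a in b, and the breakpoint count
    (adjacencies of a absent from b)."""
    if a.has_duplication or b.has_duplication:
        raise ValueError("breakpoint comparison requires duplication-free orders")
    if {abs(g) for g in a.genes} != {abs(g) for g in b.genes}:
        raise ValueError("orders have unequal gene content")
    sa, sb = _adjacency_set(a.genes), _adjacency_set(b.genes)
    shared = sa & sb
    return shared, len(sa) - len(shared)


# ---------------------------------------------------------------------------
# Blocks

@dataclass(frozen=True)
class BlockPartition:
    """The conserved three-block layout: forward / reverse / forward."""

    blocks: tuple[tuple[str, ...], ...]
    strands: tuple[str, ...]


def three_block_partition(order: GeneOrder) -> BlockPartition:
    """Partition a normalized order into its maximal same-strand runs."""
    order = normalize(order)
    blocks: list[list[int]] = []
    strands: list[str] = []
    for g in order.genes:
        s = "+" if g > 0 else "-"
        if strands and strands[-1] == s:
            blocks[-1].append(g)
        else:
            blocks.append([g])
            strands.append(s)
    return BlockPartition(
        blocks=tuple(tuple(vocab.ID_GENE[abs(g)] for g in b) for b in blocks),
        strands=tuple(strands),
    )


def _circular_windows(n: int):
    for length in range(2, n):  # proper intervals only
        for start in range(n):
            yield start, length


def _is_contiguous(gene_set: frozenset[int], order: GeneOrder) -> bool:
    pos = [i for i, g in enumerate(order.genes) if abs(g) in gene_set]
    if len(pos) != len(gene_set):
        return False
    n = len(order.genes)
    k = len(pos)
    if pos[-1] - pos[0] + 1 == k:
        return True
    # circular contiguity: complement must be one linear block
    comp = sorted(set(range(n)) - set(pos))
    return bool(comp) and comp[-1] - comp[0] + 1 == len(comp)


def common_intervals(orders: Sequence[GeneOrder]) -> list[frozenset[int]]:
    """All gene sets (2 <= |S| < n) contiguous in every order, by direct
    enumeration of the first order's circular windows (n <= 37 keeps this
    comfortably cheap)."""
    if len(orders) < 2:
        raise ValueError("need at least two orders")
    ref = orders[0]
    content = {abs(g) for g in ref.genes}
    for o in orders[1:]:
        if {abs(g) for g in o.genes} != content:
            raise ValueError("orders have unequal gene content")
    n = len(ref.genes)
    found: set[frozenset[int]] = set()
    for start, length in _circular_windows(n):
        idx = [(start + i) % n for i in range(length)]
        s = frozenset(abs(ref.genes[i]) for i in idx)
        if s in found:
            continue
        if all(_is_contiguous(s, o) for o in orders[1:]):
            found.add(s)
    return sorted(found, key=lambda s: (-len(s), sorted(s)))


def find_conserved_blocks(
    orders: Sequence[GeneOrder],
) -> tuple[list[tuple[str, ...]], list[str]]:
    """Conserved blocks shared by all orders, plus the variable genes.

    A conserved block is a maximal run of genes whose signed circular
    adjacencies are shared by every order — each such run is contiguous in
    every order, i.e. a (signed) common interval, and the runs partition
    the circle.  Blocks are returned as signed label tuples in the first
    order's arrangement; genes left in singleton runs are the variable
    (rearranging) part.  Two identical orders yield one block spanning the
    whole genome.
    """
    if len(orders) < 2:
        raise ValueError("need at least two orders")
    ref = normalize(orders[0])
    content = {abs(g) for g in ref.genes}
    adj = _adjacency_set(ref.genes)
    for o in orders[1:]:
        if {abs(g) for g in o.genes} != content:
            raise ValueError("orders have unequal gene content")
        adj &= _adjacency_set(o.genes)
    n = len(ref.genes)
    cuts = [
        (i + 1) % n for i in range(n)
        if min((ref.genes[i], ref.genes[(i + 1) % n]),
               (-ref.genes[(i + 1) % n], -ref.genes[i])) not in adj
    ]
    if not cuts:
        return [tuple(ref.labels)], []
    cuts.sort()
    runs: list[list[int]] = []
    for k, start in enumerate(cuts):
        end = cuts[(k + 1) % len(cuts)]
        idx = start
        run = []
        while True:
            run.append(ref.genes[idx])
            idx = (idx + 1) % n
            if idx == end:
                break
        runs.append(run)
    blocks = [
        tuple(signed_label(g) for g in run) for run in runs if len(run) >= 2
    ]
    variable = [
        vocab.ID_GENE[abs(run[0])] for run in runs if len(run) == 1
    ]
    return blocks, variable


# ---------------------------------------------------------------------------
# Text format + reference orders

def read_orders(path: str | Path) -> dict[str, GeneOrder]:
    """Read the gene-order text format: ``id<TAB>cox1,cox2,-F,...`` lines."""
    orders: dict[str, GeneOrder] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected id<TAB>gene,gene,...")
        oid, tokens = parts[0], parts[-1].split(",")
        orders[oid] = order_from_labels(oid, tokens)
    return orders


def write_orders(path: str | Path, orders: Iterable[GeneOrder]) -> None:
    lines = [f"{o.id}\t{o}" for o in sorted(orders, key=lambda o: o.id)]
    Path(path).write_text("\n".join(lines) + "\n")


def reference_orders() -> dict[str, GeneOrder]:
    """Bundled reference arrangements (ancestral aculiferan lineages and
    tip orders derivable from published descriptions), with provenance tags
    in the data file."""
    text = resources.files("mitorder.data").joinpath("reference_orders.tsv").read_text()
    orders: dict[str, GeneOrder] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        oid, _provenance, tokens = line.split("\t")
        orders[oid] = order_from_labels(oid, tokens.split(","))
    return orders
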