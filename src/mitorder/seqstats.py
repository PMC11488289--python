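"""Descriptive mitogenome statistics.

Covers nucleotide composition and strand skews (AT-skew = (A-T)/(A+T),
GC-skew = (G-C)/(G+C)), codon usage of the protein-coding genes under the
invertebrate mitochondrial code (start/stop tallies, RSCU, amino-acid
frequencies, codon-position AT%), the inventory of intergenic non-coding
regions (NCRs) and gene overlaps on the circular coordinate, and exact
tandem-repeat motif arrays in NCR sequences.

``N`` bases (placeholder gaps of two-contig assemblies) are excluded from
all percentages and skews.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from .annotate import STOP_CODONS, CodonRecord
from .model import AnnotatedGenome, Feature

INVERTEBRATE_MITO_TABLE = 5


# ---------------------------------------------------------------------------
# Composition

@dataclass(frozen=True)
class CompositionStats:
    counts: Mapping[str, int]
    gc_percent: float
    at_percent: float
    at_skew: float
    gc_skew: float

    @property
    def length(self) -> int:
        return sum(self.counts.values())


def composition(seq: str) -> CompositionStats:
    """Base counts, AT/GC percentages and strand skews of a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    c = Counter(seq)
    counts = {b: c.get(b, 0) for b in "ACGTN"}
    if set(c) - set("ACGTN"):
        raise ValueError(f"non-ACGTN characters: {sorted(set(c) - set('ACGTN'))}")
    a, t, g, cc = counts["A"], counts["T"], counts["G"], counts["C"]
    denom = a + t + g + cc  # N excluded
    at_percent = 100.0 * (a + t) / denom if denom else 0.0
    gc_percent = 100.0 * (g + cc) / denom if denom else 0.0
    at_skew = (a - t) / (a + t) if a + t else 0.0
    gc_skew = (g - cc) / (g + cc) if g + cc else 0.0
    return CompositionStats(counts, gc_percent, at_percent, at_skew, gc_skew)


# ---------------------------------------------------------------------------
# Codon usage

def synonymous_families(table_id: int = INVERTEBRATE_MITO_TABLE) -> dict[str, tuple[str, ...]]:
    """Amino acid -> codons encoding it, for the given genetic code."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fams: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(cods) for aa, cods in fams.items()}


def translate_codon(codon: str, table_id: int = INVERTEBRATE_MITO_TABLE) -> str:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


@dataclass
class CodonUsage:
    counts: Counter = field(default_factory=Counter)  # sense codons only
    start_tally: Counter = field(default_factory=Counter)
    stop_tally: Counter = field(default_factory=Counter)
    rscu: dict[str, float] = field(default_factory=dict)
    aa_freq: dict[str, float] = field(default_factory=dict)  # percent
    position_at: tuple[float, float, float] = (0.0, 0.0, 0.0)
    excluded: list[str] = field(default_factory=list)  # genes left out of rscu


def _gene_codons(
    seq: str, record: CodonRecord | None
) -> tuple[list[str], str | None, str | None]:
    """Split a coding-strand PCG sequence into sense codons + start/stop."""
    rem = len(seq) % 3
    tail = seq[len(seq) - rem :] if rem else ""
    body = seq[: len(seq) - rem]
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    stop = None
    if record is not None and record.truncated:
        stop = record.stop_codon  # "T(AA)" / "TA(A)"; tail is the truncated stop
    elif codons and codons[-1] in STOP_CODONS:
        stop = codons.pop()
    elif record is not None:
        stop = record.stop_codon
    start = codons[0] if codons else None
    if rem and (record is None or not record.truncated):
        # leftover bases that are not a documented truncated stop
        return codons, start, stop
    return codons, start, stop


def codon_usage(
    genome: AnnotatedGenome,
    pcgs: Sequence[Feature],
    codon_records: Mapping[str, CodonRecord] | None = None,
    table_id: int = INVERTEBRATE_MITO_TABLE,
) -> CodonUsage:
    """Aggregate codon usage over curated PCGs, read on their coding strands.

    RSCU for codon c in a synonymous family of size k with counts n is
    ``RSCU_c = n_c * k / sum(n_family)``; families with zero total get RSCU 0
    for every member.  Stop codons are tallied separately and excluded from
    RSCU.  A PCG whose length is not a codon multiple after truncated-stop
    removal is excluded from the codon pools and listed in ``excluded``.
    """
    usage = CodonUsage()
    records = codon_records or {}
    pooled: list[str] = []
    for f in sorted(pcgs, key=lambda f: (f.start, f.label)):
        if f.ftype != "PCG":
            continue
        record = records.get(f.label)
        seq = genome.feature_seq(f)
        rem = len(seq) % 3
        if rem and (record is None or not record.truncated):
            usage.excluded.append(f.label)
            continue
        codons, start, stop = _gene_codons(seq, record)
        if "N" in seq:
            usage.excluded.append(f.label)
            continue
        if start:
            usage.start_tally[start] += 1
        if stop:
            usage.stop_tally[stop] += 1
        pooled.extend(codons)

    usage.counts = Counter(pooled)
    fams = synonymous_families(table_id)
    for aa, codons in fams.items():
        total = sum(usage.counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            usage.rscu[c] = usage.counts.get(c, 0) * k / total if total else 0.0

    n_codons = len(pooled)
    if n_codons:
        aa_counts = Counter(translate_codon(c, table_id) for c in pooled)
        usage.aa_freq = {
            aa: 100.0 * aa_counts.get(aa, 0) / n_codons for aa in sorted(fams)
        }
        at = [0, 0, 0]
        for codon in pooled:
            for p in range(3):
                if codon[p] in "AT":
                    at[p] += 1
        usage.position_at = tuple(100.0 * x / n_codons for x in at)
    return usage


# ---------------------------------------------------------------------------
# NCRs and overlaps

@dataclass(frozen=True)
class NCRRecord:
    flank_upstream: str
    flank_downstream: str
    start: int
    end: int  # may exceed genome length for the origin-spanning NCR
    length: int
    at_percent: float


def _covered_intervals(
    features: Iterable[Feature], length: int
) -> list[tuple[int, int]]:
    """Feature spans mapped into [0, length) (wrapping spans split in two)."""
    ivals: list[tuple[int, int]] = []
    for f in features:
        if f.end <= length:
            ivals.append((f.start, f.end))
        else:
            ivals.append((f.start, length))
            ivals.append((0, f.end - length))
    return sorted(ivals)


def _merge(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def find_ncrs(
    genome: AnnotatedGenome, features: Sequence[Feature] | None = None
) -> list[NCRRecord]:
    """Maximal intervals covered by no feature, on the circular coordinate.

    The origin-spanning gap (if any) is reported once, with ``end`` beyond
    the genome length.  All gaps >= 1 bp are returned; see
    :func:`summarize_ncrs` for the printed size classes.
    """
    feats = [f for f in (features if features is not None else genome.features)
             if f.ftype != "NCR"]
    n = genome.length
    if not feats:
        comp = composition(genome.sequence)
        return [NCRRecord("", "", 0, n, n, comp.at_percent)]
    covered = _merge(_covered_intervals(feats, n))

    gaps: list[tuple[int, int]] = []
    for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
        if s2 > e1:
            gaps.append((e1, s2))
    # wrap-around gap between the last covered end and the first covered start
    first_s, last_e = covered[0][0], covered[-1][1]
    if genome.circular:
        if last_e < n or first_s > 0:
            wrap_len = (n - last_e) + first_s
            if wrap_len > 0:
                gaps.append((last_e, n + first_s) if last_e < n else (0, first_s))
    else:
        if first_s > 0:
            gaps.insert(0, (0, first_s))
        if last_e < n:
            gaps.append((last_e, n))

    starts = {}
    ends = {}
    for f in sorted(feats, key=lambda f: (f.start, f.label)):
        ends.setdefault(f.end % n, f.label)
        starts.setdefault(f.start % n, f.label)

    records = []
    for s, e in gaps:
        seq = genome.span_seq(s, e)
        comp = composition(seq)
        records.append(NCRRecord(
            flank_upstream=ends.get(s % n, ""),
            flank_downstream=starts.get(e % n, ""),
            start=s, end=e, length=e - s, at_percent=comp.at_percent,
        ))
    records.sort(key=lambda r: r.start)
    return records


def summarize_ncrs(ncrs: Sequence[NCRRecord], genome_length: int) -> dict:
    total = sum(r.length for r in ncrs)
    return {
        "n_ncrs": len(ncrs),
        "n_gt10": sum(1 for r in ncrs if r.length > 10),
        "n_gt100": sum(1 for r in ncrs if r.length > 100),
        "total_bp": total,
        "percent_of_genome": 100.0 * total / genome_length,
    }


def at_richest_ncr(ncrs: Sequence[NCRRecord]) -> NCRRecord:
    """The NCR with the highest AT%; ties go to the longer, then leftmost.

    In these genomes this is the usual flag for the control region / origin
    of replication.
    """
    if not ncrs:
        raise ValueError("no NCRs")
    return max(ncrs, key=lambda r: (r.at_percent, r.length, -r.start))


@dataclass(frozen=True)
class OverlapRecord:
    gene_a: str
    gene_b: str
    length: int


def find_overlaps(
    genome: AnnotatedGenome, features: Sequence[Feature] | None = None
) -> tuple[list[OverlapRecord], int]:
    """Positional overlaps between feature pairs on the circle.

    Overlap is measured on plus-strand coordinates regardless of the strand
    of either gene.  Returns one record per unordered pair with >= 1 bp
    intersection, plus the total overlapping bp.
    """
    feats = [f for f in (features if features is not None else genome.features)
             if f.ftype != "NCR"]
    n = genome.length
    spans = {
        id(f): _merge(_covered_intervals([f], n)) for f in feats
    }
    records = []
    ordered = sorted(feats, key=lambda f: (f.start, f.end, f.label))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            olap = 0
            for s1, e1 in spans[id(a)]:
                for s2, e2 in spans[id(b)]:
                    olap += max(0, min(e1, e2) - max(s1, s2))
            if olap >= 1:
                records.append(OverlapRecord(a.label, b.label, olap))
    return records, sum(r.length for r in records)


# ---------------------------------------------------------------------------
# Tandem motif arrays

@dataclass(frozen=True)
class MotifArray:
    """An exact tandem repeat: ``unit`` repeated ``copies`` times plus an
    optional partial copy of ``partial_tail`` bp, starting at ``start``.

    ``unit`` is stored in the phase actually laid down in the sequence (so
    the substring invariant holds exactly); :attr:`canonical_unit` gives the
    lexicographically least rotation for cross-genome comparison.
    """

    unit: str
    copies: int
    partial_tail: int
    start: int

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def total_length(self) -> int:
        return self.copies * len(self.unit) + self.partial_tail

    @property
    def end(self) -> int:
        return self.start + self.total_length

    @property
    def canonical_unit(self) -> str:
        u = self.unit
        return min(u[i:] + u[:i] for i in range(len(u)))


def find_tandem_motifs(
    seq: str, min_unit: int = 6, max_unit: int = 30, min_copies: int = 2
) -> list[MotifArray]:
    """Exact tandem arrays in a sequence (typically one NCR).

    Overlapping candidates are resolved by keeping the array of maximal
    total length, ties by smaller unit length, then leftmost start.
    """
    seq = seq.upper()
    n = len(seq)
    candidates: list[MotifArray] = []
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        i = 0
        while i + 2 * u <= n:
            if seq[i : i + u] != seq[i + u : i + 2 * u]:
                i += 1
                continue
            unit = seq[i : i + u]
            c = 2
            while seq[i + c * u : i + (c + 1) * u] == unit:
                c += 1
            tail = 0
            while (i + c * u + tail < n and tail < u
                   and seq[i + c * u + tail] == unit[tail]):
                tail += 1
            if c >= min_copies:
                candidates.append(MotifArray(unit, c, tail, i))
            # a longer array with this unit length cannot restart inside
            i += (c - 1) * u + tail + 1
    candidates.sort(key=lambda m: (-m.total_length, m.unit_length, m.start))
    kept: list[MotifArray] = []
    for m in candidates:
        if all(m.end <= k.start or k.end <= m.start for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.start)
    return kept
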