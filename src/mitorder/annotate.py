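"""Reconciliation and boundary editing of multi-annotator feature calls.

The curation protocol, in order:

1. tRNA reconciliation — a tRNA is accepted iff it was called with the same
   canonical label, on the same strand, with >= 1 bp overlap by at least two
   annotator sources (evidence ``dual``), or by a single source whose
   secondary-structure string shows at least an acceptor stem and an
   anticodon arm (evidence ``single+cloverleaf``).  The acceptance of
   D-armless structures is deliberate: the serine isoacceptors S1/S2 (and
   several other mitochondrial tRNAs) lack the D-arm yet are genuine.
2. PCG boundary editing — the start is moved downstream to the first start
   codon (ATG/ATA/ATT/TTG/GTG, invertebrate mitochondrial code) inside the
   called span; the end is set at the first in-frame TAA/TAG, or truncated
   to T/TA when a validated tRNA begins within 2 bp downstream (the stop is
   then completed post-transcriptionally by polyadenylation and recorded as
   ``T(AA)``/``TA(A)``).  PCGs may overlap only in different reading frames.
3. rRNA extension — each rRNA is widened outward until it abuts its nearest
   flanking accepted feature of any type (rRNAs are typically flanked by
   tRNAs, e.g. trnV between rrnL and rrnS), without creating new overlaps.

Running the full curation on its own output reproduces it (idempotence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .model import AnnotatedGenome, Feature

#: A single annotator feature call: a Feature whose ``source`` identifies the
#: annotator and whose ``structure`` optionally carries its dot-bracket string.
AnnotatorCall = Feature

START_CODONS = ("ATG", "ATA", "ATT", "TTG", "GTG")
STOP_CODONS = ("TAA", "TAG")
#: a truncated stop is honoured only if a validated tRNA begins within this
#: many bp downstream of it (no window is universally agreed; 2 bp is strict)
TRUNCATED_STOP_WINDOW = 2
#: an in-frame stop earlier than this many codons marks a putative pseudogene
MIN_ORF_CODONS = 30


@dataclass(frozen=True)
class CodonRecord:
    """Start/stop codon bookkeeping for one curated PCG."""

    gene: str
    start_codon: str | None
    stop_codon: str | None  # "TAA", "TAG", "T(AA)", "TA(A)" or None
    truncated: bool = False
    n_codons: int = 0  # complete codons including start, excluding stop


@dataclass
class CurationResult:
    accepted: list[Feature] = field(default_factory=list)
    rejected: list[tuple[Feature, str]] = field(default_factory=list)
    codon_records: dict[str, CodonRecord] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tRNA secondary structure

def _pair_table(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure string")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"bad structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced structure string")
    return sorted(pairs)


def _helices(pairs: Sequence[tuple[int, int]], min_bp: int = 3):
    """Group stacked base pairs into helices of >= ``min_bp`` pairs."""
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:
        if helices and p[0] == helices[-1][-1][0] + 1 and p[1] == helices[-1][-1][1] - 1:
            helices[-1].append(p)
        else:
            helices.append([p])
    return [h for h in helices if len(h) >= min_bp]


def detect_arms(structure: str, seq: str | None = None) -> dict[str, bool]:
    """Identify which cloverleaf arms a dot-bracket structure contains.

    The acceptor stem is the outermost helix (enclosing all others); the
    remaining hairpin stems are read 5'->3'.  With three inner stems they are
    the D-, anticodon and T-arms; with fewer, the anticodon arm is the stem
    whose loop lies closest to the middle of the molecule and the others are
    assigned to the D (before) or T (after) side.
    """
    if seq is not None and len(seq) != len(structure):
        raise ValueError("structure and sequence lengths differ")
    arms = {"acceptor": False, "D": False, "anticodon": False, "T": False}
    stems = _helices(_pair_table(structure))
    if not stems:
        return arms
    outer = min(stems, key=lambda h: h[0][0])
    inner = [h for h in stems if h is not outer]
    encloses = all(outer[0][0] < h[0][0] and h[0][1] < outer[0][1] for h in inner)
    if encloses and inner:
        arms["acceptor"] = True
    elif encloses and not inner:
        # a single helix: treat as acceptor stem only
        arms["acceptor"] = True
        return arms
    else:
        inner = stems  # no enclosing helix: no acceptor, all stems are inner
    if not inner:
        return arms
    if len(inner) >= 3:
        arms["D"] = arms["anticodon"] = arms["T"] = True
        return arms
    # the anticodon loop sits near the middle of the region the acceptor
    # stem encloses (the raw sequence midpoint is skewed by the 3' tail)
    if arms["acceptor"]:
        mid = (outer[0][0] + outer[0][1]) / 2
    else:
        mid = len(structure) / 2

    def loop_centre(h) -> float:
        return (h[-1][0] + h[-1][1]) / 2

    ac = min(inner, key=lambda h: abs(loop_centre(h) - mid))
    arms["anticodon"] = True
    for h in inner:
        if h is ac:
            continue
        if loop_centre(h) < loop_centre(ac):
            arms["D"] = True
        else:
            arms["T"] = True
    return arms


# ---------------------------------------------------------------------------
# tRNA reconciliation

def _overlap_len(a: Feature, b: Feature) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def _cluster_by_locus(calls: list[Feature]) -> list[list[Feature]]:
    """Group same-label calls into loci: same strand, >= 1 bp overlap."""
    clusters: list[list[Feature]] = []
    for call in sorted(calls, key=lambda f: (f.start, f.end, f.source)):
        for cluster in clusters:
            if any(c.strand == call.strand and _overlap_len(c, call) >= 1
                   for c in cluster):
                cluster.append(call)
                break
        else:
            clusters.append([call])
    return clusters


def _preferred_call(cluster: list[Feature], priority: Sequence[str] | None) -> Feature:
    """Pick the span-defining call: explicit source priority first, then the
    structure-bearing source, then deterministic source order."""
    if priority:
        for src in priority:
            hits = [c for c in cluster if c.source == src]
            if hits:
                return hits[0]
    with_structure = [c for c in cluster if c.structure]
    pool = with_structure or cluster
    return sorted(pool, key=lambda c: (c.source, c.start))[0]


def _has_core_structure(call: Feature) -> bool:
    if not call.structure:
        return False
    arms = detect_arms(call.structure)
    return arms["acceptor"] and arms["anticodon"]


def reconcile_trnas(
    calls: Iterable[AnnotatorCall], priority: Sequence[str] | None = None
) -> CurationResult:
    """Apply the dual-evidence / single-plus-structure acceptance rule."""
    result = CurationResult()
    by_label: dict[str, list[Feature]] = {}
    for call in calls:
        if call.ftype != "tRNA":
            raise ValueError(f"non-tRNA call {call.label} passed to reconcile_trnas")
        by_label.setdefault(call.label, []).append(call)

    accepted_by_label: dict[str, list[Feature]] = {}
    for label in sorted(by_label):
        for cluster in _cluster_by_locus(by_label[label]):
            sources = {c.source for c in cluster}
            if len(sources) >= 2:
                chosen = _preferred_call(cluster, priority)
                accepted_by_label.setdefault(label, []).append(
                    chosen.with_flags("evidence:dual")
                )
            else:
                structured = [c for c in cluster if _has_core_structure(c)]
                if structured:
                    accepted_by_label.setdefault(label, []).append(
                        structured[0].with_flags("evidence:single+cloverleaf")
                    )
                else:
                    reason = (
                        "single-evidence, no structure" if not any(
                            c.structure for c in cluster)
                        else "single-evidence, structure lacks acceptor/anticodon arms"
                    )
                    for c in cluster:
                        result.rejected.append((c, reason))

    for label, feats in accepted_by_label.items():
        if len(feats) > 1:
            feats = [f.with_flags("putative duplication") for f in feats]
        result.accepted.extend(feats)
    result.accepted.sort(key=lambda f: (f.start, f.end, f.label))
    return result


# ---------------------------------------------------------------------------
# PCG boundary editing

def _norm_span(start: int, end: int, length: int) -> tuple[int, int]:
    while start >= length:
        start -= length
        end -= length
    while start < 0:
        start += length
        end += length
    return start, end


def _trna_downstream(
    pos: int, strand: str, trnas: Sequence[Feature], length: int,
    window: int = TRUNCATED_STOP_WINDOW,
) -> bool:
    """Is there a validated tRNA starting within ``window`` bp downstream of
    coding-strand position ``pos`` (a plus-strand coordinate)?"""
    for t in trnas:
        if strand == "+":
            gap = (t.start - pos) % length
        else:
            gap = (pos - t.end) % length
        if gap <= window:
            return True
    return False


def refine_pcg(
    genome: AnnotatedGenome,
    call: Feature,
    validated_trnas: Sequence[Feature] = (),
) -> tuple[Feature, CodonRecord | None]:
    """Edit one PCG call's boundaries; return the feature + codon record."""
    if call.ftype != "PCG":
        raise ValueError(f"{call.label}: refine_pcg expects a PCG call")
    seq = genome.feature_seq(call)
    n = genome.length

    start_off = None
    for i in range(0, len(seq) - 2):
        if seq[i : i + 3] in START_CODONS:
            start_off = i
            break
    if start_off is None:
        return call.with_flags("no-start"), None
    start_codon = seq[start_off : start_off + 3]

    stop_off = None
    stop_codon = None
    flags: list[str] = []
    for j in range(start_off + 3, len(seq) - 2, 3):
        if seq[j : j + 3] in STOP_CODONS:
            stop_off = j
            stop_codon = seq[j : j + 3]
            break

    if stop_off is not None:
        end_off = stop_off + 3
        truncated = False
        if (stop_off - start_off) // 3 < MIN_ORF_CODONS:
            flags.append("pseudo?")
    else:
        rem = (len(seq) - start_off) % 3
        tail = seq[len(seq) - rem :] if rem else ""
        end_off = len(seq)
        truncated = False
        if call.strand == "+":
            stop_pos = call.end  # plus-strand coordinate just past the tail
        else:
            stop_pos = call.start
        if rem == 1 and tail == "T" and _trna_downstream(
            stop_pos, call.strand, validated_trnas, n
        ):
            stop_codon, truncated = "T(AA)", True
        elif rem == 2 and tail == "TA" and _trna_downstream(
            stop_pos, call.strand, validated_trnas, n
        ):
            stop_codon, truncated = "TA(A)", True
        else:
            end_off = len(seq) - rem  # trim incomplete tail, no stop found
            flags.append("no-stop")

    if call.strand == "+":
        new_start, new_end = call.start + start_off, call.start + end_off
    else:
        new_start, new_end = call.end - end_off, call.end - start_off
    new_start, new_end = _norm_span(new_start, new_end, n)

    refined = replace(call, start=new_start, end=new_end)
    if flags:
        refined = refined.with_flags(*flags)
    n_codons = (end_off - start_off) // 3 - (0 if truncated or stop_off is None else 1)
    record = CodonRecord(
        gene=call.label, start_codon=start_codon, stop_codon=stop_codon,
        truncated=truncated, n_codons=n_codons,
    )
    return refined, record


def _frame_compatible(a: Feature, b: Feature) -> bool:
    """True if two overlapping PCGs are in different frames or strands."""
    if a.strand != b.strand:
        return True
    if a.strand == "+":
        return (a.start - b.start) % 3 != 0
    return (a.end - b.end) % 3 != 0


# ---------------------------------------------------------------------------
# rRNA extension

def extend_rrna(
    features: Sequence[Feature], genome_length: int, circular: bool = True
) -> list[Feature]:
    """Widen each rRNA outward to abut its nearest flanking feature.

    Boundaries already abutting (or overlapping) a neighbour are left alone,
    so the operation is idempotent and never creates new overlaps.
    """
    out: list[Feature] = []
    for f in features:
        if f.ftype != "rRNA":
            out.append(f)
            continue
        others = [o for o in features if o is not f]
        if not others:
            out.append(f.with_flags("no-flank:5'", "no-flank:3'"))
            continue
        if circular:
            gap_up = min((f.start - o.end) % genome_length for o in others)
            gap_down = min((o.start - f.end) % genome_length for o in others)
        else:
            ups = [f.start - o.end for o in others if o.end <= f.start]
            downs = [o.start - f.end for o in others if o.start >= f.end]
            gap_up = min(ups) if ups else None
            gap_down = min(downs) if downs else None
        flags: list[str] = []
        start, end = f.start, f.end
        if gap_up is None:
            flags.append("no-flank:5'")
        elif gap_up > 0:
            start -= gap_up
        if gap_down is None:
            flags.append("no-flank:3'")
        elif gap_down > 0:
            end += gap_down
        start, end = _norm_span(start, end, genome_length)
        g = replace(f, start=start, end=end)
        if flags:
            g = g.with_flags(*flags)
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# Full protocol

def curate(
    genome: AnnotatedGenome,
    calls: Iterable[AnnotatorCall],
    priority: Sequence[str] | None = None,
) -> CurationResult:
    """Run the full reconciliation + boundary-editing protocol."""
    calls = list(calls)
    trna_calls = [c for c in calls if c.ftype == "tRNA"]
    pcg_calls = [c for c in calls if c.ftype == "PCG"]
    rrna_calls = [c for c in calls if c.ftype == "rRNA"]
    other = [c for c in calls if c.ftype not in ("tRNA", "PCG", "rRNA")]

    result = reconcile_trnas(trna_calls, priority)
    trnas = list(result.accepted)

    # one representative call per PCG label, then boundary editing
    pcgs: list[Feature] = []
    by_label: dict[str, list[Feature]] = {}
    for c in pcg_calls:
        by_label.setdefault(c.label, []).append(c)
    for label in sorted(by_label):
        for cluster in _cluster_by_locus(by_label[label]):
            chosen = _preferred_call(cluster, priority)
            refined, record = refine_pcg(genome, chosen, trnas)
            if record is None:
                result.rejected.append((refined, "no start codon in span"))
                continue
            pcgs.append(refined)
            result.codon_records[label] = record

    # PCGs may overlap only if reading frames differ
    pcgs.sort(key=lambda f: (f.start, f.end))
    valid_pcgs: list[Feature] = []
    for f in pcgs:
        clash = [
            v for v in valid_pcgs
            if _overlap_len(v, f) >= 1 and not _frame_compatible(v, f)
        ]
        if clash:
            result.rejected.append((f, "same-frame overlap with " + clash[0].label))
        else:
            valid_pcgs.append(f)

    # rRNAs: pick one call per label, then extend against everything accepted
    rrnas: list[Feature] = []
    by_label = {}
    for c in rrna_calls:
        by_label.setdefault(c.label, []).append(c)
    for label in sorted(by_label):
        for cluster in _cluster_by_locus(by_label[label]):
            rrnas.append(_preferred_call(cluster, priority))

    pool = trnas + valid_pcgs + rrnas + list(other)
    extended = extend_rrna(pool, genome.length, genome.circular)

    result.accepted = sorted(extended, key=lambda f: (f.start, f.end, f.label))
    return result
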