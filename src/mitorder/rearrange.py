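"""Most-parsimonious rearrangement scenarios between two gene orders.

Event repertoire (the classic mitogenome rearrangement vocabulary):

``i``
    inversion — a contiguous segment is reversed and strand-flipped;
``t``
    transposition — a contiguous segment is excised and reinserted
    elsewhere, signs kept;
``iT``
    inverse transposition — moved *and* inverted in one event;
``tdrl``
    tandem-duplication–random-loss — a segment is duplicated in tandem and
    one copy of each gene is lost, so the segment is re-sorted into a
    "keep-first" subsequence followed by a "keep-second" subsequence
    (signs kept; one event regardless of segment length);
``dupl``
    duplication, report-only.

Inference strategy: shared signed adjacencies are collapsed into supergenes
(relabelling the target to the identity permutation), single events are
recognised analytically from the mismatch window, and deeper scenarios come
from bounded breadth-first search over event applications — exhaustive on
small reduced alphabets, breakpoint-guided with a beam on larger ones.  All
co-optimal scenarios are reported (capped), with ties ordered by event-kind
priority i < t < iT < tdrl and then lexicographic operands.

Cost is the event count and is *directional* (tdrl cannot be inverted by a
tdrl), so inference is always oriented ancestral -> derived.  Orders are
linearised at the normalisation anchor (cox1); events never span the
anchor — the rearrangements modelled here all lie within the gene blocks.

The exhaustive :func:`bfs_oracle` is an independent reference for testing:
plain breadth-first enumeration of raw event applications with no supergene
reduction and no analytic detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .gene_order import GeneOrder, normalize, parse_signed_label, signed_label

SignedGenes = tuple[int, ...]

KIND_PRIORITY = {"i": 0, "t": 1, "iT": 2, "tdrl": 3, "dupl": 4}


# ---------------------------------------------------------------------------
# Events (public, gene-labelled)

@dataclass(frozen=True)
class Event:
    """One rearrangement operation, described by its operand genes.

    ``genes`` is the moved/inverted/duplicated segment as it reads in the
    order the event applies to; ``after`` names the signed gene the segment
    lands after (``None`` = in front of the whole linearised order) for
    ``t``/``iT``; ``keep_first`` is the tdrl subset kept from the first
    tandem copy.
    """

    kind: str
    genes: tuple[str, ...]
    after: str | None = None
    keep_first: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KIND_PRIORITY:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "tdrl":
            kf = {t.lstrip("-") for t in self.keep_first}
            seg = [t.lstrip("-") for t in self.genes]
            if not kf or not set(seg) >= kf or len(kf) == len(seg):
                raise ValueError("tdrl keep_first must be a proper non-empty "
                                 "subset of the segment")

    def sort_key(self):
        return (KIND_PRIORITY[self.kind], self.genes, self.after or "",
                self.keep_first)


def _revflip(genes: SignedGenes) -> SignedGenes:
    return tuple(-g for g in reversed(genes))


def _locate(genes: SignedGenes, seg_abs: tuple[int, ...]) -> int:
    k = len(seg_abs)
    for i in range(len(genes) - k + 1):
        if tuple(abs(g) for g in genes[i : i + k]) == seg_abs:
            return i
    raise ValueError("event operand is not a contiguous segment of the order")


def apply_event(order: GeneOrder, event: Event) -> GeneOrder:
    """Apply one event to a gene order (linearised as stored)."""
    genes = order.genes
    seg_abs = tuple(abs(parse_signed_label(t)) for t in event.genes)
    i = _locate(genes, seg_abs)
    k = len(seg_abs)
    seg = genes[i : i + k]

    if event.kind == "i":
        new = genes[:i] + _revflip(seg) + genes[i + k :]
    elif event.kind in ("t", "iT"):
        rest = genes[:i] + genes[i + k :]
        if event.after is None:
            dest = 0
        else:
            a = abs(parse_signed_label(event.after))
            dest = next(p for p, g in enumerate(rest) if abs(g) == a) + 1
        moved = _revflip(seg) if event.kind == "iT" else seg
        new = rest[:dest] + moved + rest[dest:]
    elif event.kind == "tdrl":
        kf = {abs(parse_signed_label(t)) for t in event.keep_first}
        first = tuple(g for g in seg if abs(g) in kf)
        second = tuple(g for g in seg if abs(g) not in kf)
        new = genes[:i] + first + second + genes[i + k :]
    elif event.kind == "dupl":
        new = genes[: i + k] + seg + genes[i + k :]
        return replace(order, genes=new, has_duplication=True)
    else:  # pragma: no cover
        raise ValueError(event.kind)
    return replace(order, genes=new)


# ---------------------------------------------------------------------------
# Scenarios

@dataclass
class Scenario:
    """An ordered event series transforming ``source`` into ``target``."""

    source: GeneOrder
    target: GeneOrder
    events: list[Event] = field(default_factory=list)
    intermediates: list[GeneOrder] = field(default_factory=list)

    @property
    def cost(self) -> int:
        return len(self.events)

    def replays(self) -> bool:
        cur = self.source
        for ev in self.events:
            cur = apply_event(cur, ev)
        return cur.genes == self.target.genes

    def sort_key(self):
        return tuple(e.sort_key() for e in self.events)


@dataclass
class ScenarioSearchResult:
    cost: int | None
    scenarios: list[Scenario]
    exceeded: bool = False  # no scenario within max_events


# ---------------------------------------------------------------------------
# Supergene reduction

def _reduce(src: SignedGenes, tgt: SignedGenes):
    """Relabel so the target is +1..+m and collapse shared adjacencies.

    Returns ``(state, supergenes)`` where ``state`` is the reduced source
    permutation and ``supergenes[j-1]`` holds the original signed genes of
    reduced element ``j`` in target orientation.
    """
    pos = {abs(g): (i + 1, 1 if g > 0 else -1) for i, g in enumerate(tgt)}
    s = []
    for g in src:
        p, sgn = pos[abs(g)]
        s.append(p * sgn * (1 if g > 0 else -1))
    runs: list[list[int]] = [[s[0]]]
    for v in s[1:]:
        if v == runs[-1][-1] + 1:
            runs[-1].append(v)
        else:
            runs.append([v])
    # each run covers an ascending span of target positions
    spans = []
    for run in runs:
        lo, hi = min(abs(v) for v in run), max(abs(v) for v in run)
        spans.append((lo, hi, 1 if run[0] > 0 else -1))
    order_of = {span[0]: j + 1 for j, span in enumerate(sorted(spans))}
    state = tuple(order_of[lo] * sgn for lo, hi, sgn in spans)
    supergenes = [
        tuple(tgt[p] for p in range(lo - 1, hi))
        for lo, hi, _ in sorted(spans)
    ]
    return state, supergenes


def _expand(state: SignedGenes, supergenes) -> SignedGenes:
    out: list[int] = []
    for v in state:
        seg = supergenes[abs(v) - 1]
        out.extend(seg if v > 0 else _revflip(seg))
    return tuple(out)


# ---------------------------------------------------------------------------
# Internal positional events on reduced permutations

def _iapply(state: SignedGenes, ev) -> SignedGenes:
    kind, i, j = ev[0], ev[1], ev[2]
    seg = state[i : j + 1]
    if kind == "i":
        return state[:i] + _revflip(seg) + state[j + 1 :]
    if kind in ("t", "iT"):
        dest = ev[3]
        rest = state[:i] + state[j + 1 :]
        moved = _revflip(seg) if kind == "iT" else seg
        return rest[:dest] + moved + rest[dest:]
    if kind == "tdrl":
        first = ev[3]
        fset = set(first)
        a = tuple(g for g in seg if g in fset)
        b = tuple(g for g in seg if g not in fset)
        return state[:i] + a + b + state[j + 1 :]
    raise ValueError(kind)  # pragma: no cover


def detect_single_events(state: SignedGenes) -> list[tuple]:
    """All single events turning ``state`` into the identity +1..+m.

    Analytic: the operand must lie in the mismatch window, so inversions,
    edge-block transpositions/inverse transpositions and value-split tdrls
    are checked directly instead of enumerating the full event space.
    """
    m = len(state)
    ident = tuple(range(1, m + 1))
    if state == ident:
        return []
    a = next(p for p in range(m) if state[p] != p + 1)
    b = next(p for p in range(m - 1, -1, -1) if state[p] != p + 1)
    w = state[a : b + 1]
    idw = ident[a : b + 1]
    evs: list[tuple] = []
    if _revflip(w) == idw:
        evs.append(("i", a, b))
    for L in range(1, len(w)):
        X, Y = w[:L], w[L:]
        if Y + X == idw:
            evs.append(("t", a, a + L - 1, b - L + 1))
            evs.append(("t", a + L, b, a))
        if Y + _revflip(X) == idw:
            evs.append(("iT", a, a + L - 1, b - L + 1))
        if _revflip(Y) + X == idw:
            evs.append(("iT", a + L, b, a))
    if all(g > 0 for g in w):
        for theta in range(a + 1, b + 1):
            first = [g for g in w if g <= theta]
            second = [g for g in w if g > theta]
            if (first and second and first == sorted(first)
                    and second == sorted(second)):
                evs.append(("tdrl", a, b, tuple(g for g in w if g <= theta)))
    return evs


def _neighbors_full(state: SignedGenes):
    """Every distinct single-event application (exhaustive)."""
    m = len(state)
    out = []
    for i in range(m):
        for j in range(i, m):
            seg = state[i : j + 1]
            new = state[:i] + _revflip(seg) + state[j + 1 :]
            if new != state:
                out.append((("i", i, j), new))
            if j - i + 1 == m:
                continue
            rest = state[:i] + state[j + 1 :]
            flipped = _revflip(seg)
            for dest in range(len(rest) + 1):
                if dest != i:
                    out.append((("t", i, j, dest), rest[:dest] + seg + rest[dest:]))
                    out.append((("iT", i, j, dest),
                                rest[:dest] + flipped + rest[dest:]))
    for i in range(m):
        for j in range(i + 1, m):
            seg = state[i : j + 1]
            wlen = len(seg)
            for mask in range(1, (1 << wlen) - 1):
                first = tuple(seg[p] for p in range(wlen) if mask >> p & 1)
                second = tuple(seg[p] for p in range(wlen) if not mask >> p & 1)
                new = state[:i] + first + second + state[j + 1 :]
                if new != state:
                    out.append((("tdrl", i, j, first), new))
    return out


def _breakpoints(state: SignedGenes) -> list[int]:
    """Boundary indices (0..m) whose adjacency disagrees with the identity."""
    m = len(state)
    bad = []
    if state[0] != 1:
        bad.append(0)
    for p in range(1, m):
        if state[p] != state[p - 1] + 1:
            bad.append(p)
    if state[-1] != m:
        bad.append(m)
    return bad


def _bp_count(state: SignedGenes) -> int:
    return len(_breakpoints(state))


def _neighbors_guided(state: SignedGenes):
    """Breakpoint-guided candidate events for larger reduced alphabets.

    Operand boundaries and insertion points are restricted to current
    breakpoints, and tdrl candidates are target-guided value splits — the
    move set a scenario making steady progress toward the target uses.
    """
    B = _breakpoints(state)
    bset = set(B)
    out = []
    segs = [(i, j) for i in B for j in B if i < j and j <= len(state)]
    for i, jb in segs:
        j = jb - 1  # segment [i, j] inclusive; boundaries i and j+1
        seg = state[i : j + 1]
        new = state[:i] + _revflip(seg) + state[j + 1 :]
        if new != state:
            out.append((("i", i, j), new))
        if len(seg) == len(state):
            continue
        rest = state[:i] + state[j + 1 :]
        flipped = _revflip(seg)
        for q in B:
            if i <= q <= j + 1:
                continue
            dest = q if q < i else q - len(seg)
            if dest != i:
                out.append((("t", i, j, dest), rest[:dest] + seg + rest[dest:]))
                out.append((("iT", i, j, dest),
                            rest[:dest] + flipped + rest[dest:]))
        if all(g > 0 for g in seg) and len(seg) >= 2:
            vals = sorted(seg)
            for theta in vals[:-1]:
                first = [g for g in seg if g <= theta]
                second = [g for g in seg if g > theta]
                if first == sorted(first) and second == sorted(second):
                    new = (state[:i] + tuple(first) + tuple(second)
                           + state[j + 1 :])
                    if new != state:
                        out.append((("tdrl", i, j, tuple(first)), new))
    return out


# ---------------------------------------------------------------------------
# Inference

def _validate_pair(source: GeneOrder, target: GeneOrder) -> None:
    if source.has_duplication or target.has_duplication:
        raise ValueError("orders with duplications cannot enter scenario "
                         "inference (mask one copy first)")
    if {abs(g) for g in source.genes} != {abs(g) for g in target.genes}:
        raise ValueError("orders have unequal gene content")


def _internal_to_event(state: SignedGenes, iev, supergenes) -> Event:
    kind, i, j = iev[0], iev[1], iev[2]
    seg_expanded = _expand(state[i : j + 1], supergenes)
    genes = tuple(signed_label(g) for g in seg_expanded)
    if kind == "i":
        return Event("i", genes)
    if kind in ("t", "iT"):
        dest = iev[3]
        rest = state[:i] + state[j + 1 :]
        if dest == 0:
            return Event(kind, genes, after=None)
        after = _expand((rest[dest - 1],), supergenes)[-1]
        return Event(kind, genes, after=signed_label(after))
    if kind == "tdrl":
        kf = _expand(tuple(iev[3]), supergenes)
        return Event("tdrl", genes, keep_first=tuple(signed_label(g) for g in kf))
    raise ValueError(kind)  # pragma: no cover


def _paths_to_scenarios(
    source: GeneOrder, target: GeneOrder,
    start_state: SignedGenes, supergenes, paths: Iterable[tuple],
    cap: int,
) -> list[Scenario]:
    scenarios = []
    for path in paths:
        events: list[Event] = []
        inters: list[GeneOrder] = []
        st = start_state
        ok = True
        for iev in path:
            try:
                events.append(_internal_to_event(st, iev, supergenes))
            except ValueError:
                ok = False
                break
            st = _iapply(st, iev)
            inters.append(replace(source, genes=_expand(st, supergenes)))
        if ok:
            scenarios.append(Scenario(source, target, events, inters))
    scenarios.sort(key=Scenario.sort_key)
    return scenarios[:cap]


def infer_scenario(
    source: GeneOrder,
    target: GeneOrder,
    max_events: int = 4,
    max_scenarios: int = 50,
    full_enum_limit: int = 9,
    beam_width: int = 4000,
) -> ScenarioSearchResult:
    """All minimum-cost event scenarios from ``source`` to ``target``.

    Shared adjacencies are collapsed first; single events are recognised by
    signature; deeper searches enumerate events exhaustively while the
    reduced alphabet has at most ``full_enum_limit`` supergenes and switch
    to breakpoint-guided candidates with a ``beam_width`` beam above that.
    Returns an explicit exceeds-bound result when nothing is found within
    ``max_events``.
    """
    _validate_pair(source, target)
    src_n, tgt_n = normalize(source), normalize(target)
    state, supergenes = _reduce(src_n.genes, tgt_n.genes)
    m = len(state)
    if m == 1:
        return ScenarioSearchResult(0, [Scenario(src_n, tgt_n, [], [])])
    if max_events < 1:
        return ScenarioSearchResult(None, [], exceeded=True)

    evs = detect_single_events(state)
    if evs:
        scenarios = _paths_to_scenarios(
            src_n, tgt_n, state, supergenes, [(e,) for e in evs], max_scenarios
        )
        return ScenarioSearchResult(1, scenarios)

    exhaustive = m <= full_enum_limit
    neighbors = _neighbors_full if exhaustive else _neighbors_guided
    frontier: dict[SignedGenes, list[tuple]] = {state: [()]}
    seen = {state}
    for depth in range(2, max_events + 1):
        nxt: dict[SignedGenes, list[tuple]] = {}
        for st, paths in frontier.items():
            for iev, ns in neighbors(st):
                if ns in seen and ns not in nxt:
                    continue  # reached at a lower depth: never on a min path
                bucket = nxt.setdefault(ns, [])
                if len(bucket) < 8:
                    for p in paths:
                        if len(bucket) >= 8:
                            break
                        bucket.append(p + (iev,))
        if not exhaustive and len(nxt) > beam_width:
            best = sorted(nxt, key=_bp_count)[:beam_width]
            nxt = {s: nxt[s] for s in best}
        hits: list[tuple] = []
        for ns, paths in nxt.items():
            finals = detect_single_events(ns)
            for f in finals:
                for p in paths:
                    hits.append(p + (f,))
        if hits:
            scenarios = _paths_to_scenarios(
                src_n, tgt_n, state, supergenes, hits, max_scenarios
            )
            return ScenarioSearchResult(depth, scenarios)
        seen.update(nxt)
        frontier = nxt
        if not frontier:
            break
    return ScenarioSearchResult(None, [], exceeded=True)


# ---------------------------------------------------------------------------
# Exhaustive oracle

def bfs_oracle(
    source: GeneOrder | SignedGenes,
    target: GeneOrder | SignedGenes,
    max_events: int = 2,
    node_cap: int = 5_000_000,
) -> int | None:
    """Exact minimum event count by exhaustive breadth-first enumeration.

    Independent of the production inference path: no supergene reduction,
    no analytic event detection — raw event applications only.  Practical
    for small instances (<= 9 genes or <= 2 events); exceeding ``node_cap``
    raises with advice to use a smaller instance.
    """
    s = source.genes if isinstance(source, GeneOrder) else tuple(source)
    t = target.genes if isinstance(target, GeneOrder) else tuple(target)
    if {abs(g) for g in s} != {abs(g) for g in t}:
        raise ValueError("orders have unequal gene content")
    if len(s) > 9 and max_events > 2:
        raise ValueError("instance too large for the exhaustive oracle; use "
                         "a smaller instance (<= 9 genes or max_events <= 2)")
    if s == t:
        return 0
    tadj = {min((x, y), (-y, -x)) for x, y in zip(t, t[1:])}

    def adj_dist(state: SignedGenes) -> int:
        return sum(
            1 for x, y in zip(state, state[1:])
            if min((x, y), (-y, -x)) not in tadj
        )

    frontier = {s}
    visited = {s}
    nodes = 0
    for depth in range(1, max_events + 1):
        new: set[SignedGenes] = set()
        for st in sorted(frontier, key=adj_dist):
            for _, nx in _neighbors_full(st):
                nodes += 1
                if nodes > node_cap:
                    raise RuntimeError(
                        "oracle node cap exceeded; use a smaller instance"
                    )
                if nx == t:
                    return depth
                new.add(nx)
        frontier = new - visited
        visited |= frontier
    return None
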