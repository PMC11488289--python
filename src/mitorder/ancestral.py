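"""Ancestral gene orders and branch events on a fixed rooted phylogeny.

The reconstruction makes the reasoning behind published ancestral-order
hypotheses explicit as candidate-set small parsimony with an event-count
metric: each internal node draws its candidate orders from the tip orders
of its subtree, the intermediates of pairwise minimum scenarios between
those tips, and any user-supplied candidates; the minimum-total-cost
assignment over those sets is then found exactly by Sankoff-style dynamic
programming (equivalent to exhaustive combination, without the blow-up).
Ties are reported, never silently broken.

Event costs are directional (tdrl is not invertible), so branch scenarios
are always inferred parent -> child; polarity follows the user's rooting
(the outgroup drawn to the root).  Tips flagged as incomplete or carrying
duplications are pruned before reconstruction with a logged notice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .gene_order import GeneOrder, adjacency_breakpoints, normalize
from .rearrange import Event, Scenario, infer_scenario


def node_key(node: dendropy.Node) -> str:
    """Stable node identifier: tip label, or '|'-joined sorted tip labels."""
    leaves = [lf.taxon.label for lf in node.leaf_iter()]
    return "|".join(sorted(leaves))


@dataclass
class LabeledTree:
    tree: dendropy.Tree
    orders: dict[str, GeneOrder]            # node key -> assigned order
    branch_events: dict[str, Scenario]      # child node key -> parent->child
    total_cost: int
    ties: list[str] = field(default_factory=list)
    unresolved: list[str] = field(default_factory=list)
    pruned: list[str] = field(default_factory=list)


@dataclass
class SynapomorphyReport:
    clade: tuple[str, ...]
    events: list[Event]
    descriptions: list[str]
    derived_order: GeneOrder | None = None


# ---------------------------------------------------------------------------
# Scoring a fixed assignment

def score_assignment(
    tree: dendropy.Tree,
    tip_orders: Mapping[str, GeneOrder],
    internal_orders: Mapping[str, GeneOrder],
    max_events: int = 4,
) -> tuple[int, dict[str, Scenario]]:
    """Total event cost of a full node->order assignment, root to tips.

    ``internal_orders`` is keyed by :func:`node_key`.  A branch whose
    scenario exceeds ``max_events`` rejects the assignment with a
    diagnostic naming the branch.
    """
    def order_of(node: dendropy.Node) -> GeneOrder:
        if node.is_leaf():
            return tip_orders[node.taxon.label]
        return internal_orders[node_key(node)]

    total = 0
    branches: dict[str, Scenario] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = order_of(node.parent_node)
        child = order_of(node)
        res = infer_scenario(parent, child, max_events=max_events)
        if res.cost is None:
            raise ValueError(
                f"branch to {node_key(node)} exceeds {max_events} events; "
                "assignment rejected"
            )
        total += res.cost
        branches[node_key(node)] = res.scenarios[0] if res.scenarios else Scenario(
            normalize(parent), normalize(child)
        )
    return total, branches


# ---------------------------------------------------------------------------
# Candidate-set small parsimony

def _usable(order: GeneOrder) -> bool:
    return order.complete and not order.has_duplication


def _pair_cost_fn(max_events: int):
    """Directional branch cost as an additive lexicographic pair.

    Primary: event count (saturating at ``max_events + 1`` when the bounded
    search finds nothing).  Secondary: signed adjacency breakpoints — a
    finer, cheap metric that separates assignments tied on event count, so
    ties surviving both components are genuine ambiguities.
    """
    cache: dict[tuple, tuple[int, int]] = {}
    penalty = max_events + 1

    def cost(a: GeneOrder, b: GeneOrder) -> tuple[int, int]:
        key = (a.genes, b.genes)
        if key not in cache:
            if a.genes == b.genes:
                cache[key] = (0, 0)
            else:
                res = infer_scenario(a, b, max_events=max_events, max_scenarios=1)
                ev = res.cost if res.cost is not None else penalty
                _, bp = adjacency_breakpoints(a, b)
                cache[key] = (ev, bp)
        return cache[key]

    return cost


def _candidate_orders(
    tips: Sequence[GeneOrder],
    max_pair_events: int,
    max_tip_pairs: int = 15,
) -> list[GeneOrder]:
    """Subtree tip orders plus intermediates of their pairwise scenarios."""
    uniq: dict[tuple, GeneOrder] = {}
    for o in tips:
        uniq.setdefault(o.genes, normalize(o))
    pool = list(uniq.values())
    pairs = list(itertools.combinations(pool, 2))[:max_tip_pairs]
    for a, b in pairs:
        for x, y in ((a, b), (b, a)):
            res = infer_scenario(x, y, max_events=max_pair_events,
                                 max_scenarios=5)
            for sc in res.scenarios:
                for inter in sc.intermediates[:-1]:
                    uniq.setdefault(inter.genes, inter)
    return list(uniq.values())


def reconstruct(
    tree: dendropy.Tree,
    tip_orders: Mapping[str, GeneOrder],
    candidates: Iterable[GeneOrder] = (),
    max_events: int = 4,
    pair_cost_events: int = 2,
) -> LabeledTree:
    """Infer internal-node gene orders minimising total branch event cost.

    ``candidates`` adds user-supplied orders to every internal node's
    candidate set.  ``pair_cost_events`` bounds the per-branch search used
    while scoring candidate assignments (deeper branches are re-inferred
    with ``max_events`` for the final event lists).
    """
    tree = tree.clone(depth=1)
    pruned = [
        label for label, o in tip_orders.items() if not _usable(o)
    ]
    if pruned:
        keep = [t for t in tree.taxon_namespace
                if t.label in tip_orders and t.label not in pruned]
        tree.retain_taxa(keep)
        tree.purge_taxon_namespace()
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(tips - set(tip_orders))
    if missing:
        raise ValueError("no gene order for tips: " + ", ".join(missing))
    if len(tips) < 3:
        raise ValueError("need at least 3 usable tip orders")

    tipmap = {t: normalize(tip_orders[t]) for t in tips}
    user = [normalize(c) for c in candidates]
    cost = _pair_cost_fn(pair_cost_events)

    # Sankoff DP over candidate sets, postorder
    cand: dict[str, list[GeneOrder]] = {}
    score: dict[str, list[tuple[int, int]]] = {}
    best_child: dict[str, list[dict[str, int]]] = {}
    for node in tree.postorder_node_iter():
        key = node_key(node)
        if node.is_leaf():
            cand[key] = [tipmap[node.taxon.label]]
            score[key] = [(0, 0)]
            continue
        subtips = [tipmap[lf.taxon.label] for lf in node.leaf_iter()]
        cs = _candidate_orders(subtips, pair_cost_events)
        seen = {c.genes for c in cs}
        for u in user:
            if u.genes not in seen:
                cs.append(u)
                seen.add(u.genes)
        cand[key] = cs
        sc: list[tuple[int, int]] = []
        bc: list[dict[str, int]] = []
        for c in cs:
            total = (0, 0)
            picks: dict[str, int] = {}
            for child in node.child_nodes():
                ck = node_key(child)
                vals = []
                for idx, cc in enumerate(cand[ck]):
                    e, b = cost(c, cc)
                    se, sb = score[ck][idx]
                    vals.append((e + se, b + sb))
                j = min(range(len(vals)), key=vals.__getitem__)
                total = (total[0] + vals[j][0], total[1] + vals[j][1])
                picks[ck] = j
            sc.append(total)
            bc.append(picks)
        score[key] = sc
        best_child[key] = bc

    root = tree.seed_node
    rkey = node_key(root)
    rvals = score[rkey]
    rbest = min(rvals)
    argmins = [i for i, v in enumerate(rvals) if v == rbest]
    # Equally parsimonious root arrangements are genuinely ambiguous on a
    # rooted tree without extra polarity information: a single invertible
    # event on the root edge can sit on either side at the same cost.  The
    # primary pick is the first minimum-cost candidate in candidate order
    # (subtree tip orders first); every co-optimal alternative is reported
    # in ``ties`` rather than silently discarded.
    ties = [str(cand[rkey][i]) for i in argmins[1:]]

    # traceback
    orders: dict[str, GeneOrder] = {}
    choice: dict[str, int] = {rkey: argmins[0]}
    for node in tree.preorder_node_iter():
        key = node_key(node)
        idx = choice[key]
        orders[key] = cand[key][idx]
        if not node.is_leaf():
            for child in node.child_nodes():
                choice[node_key(child)] = best_child[key][idx][node_key(child)]

    # final per-branch scenarios at the full event bound
    branch_events: dict[str, Scenario] = {}
    unresolved: list[str] = []
    total_cost = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        key = node_key(node)
        res = infer_scenario(orders[node_key(node.parent_node)], orders[key],
                             max_events=max_events)
        if res.cost is None:
            unresolved.append(key)
            continue
        total_cost += res.cost
        branch_events[key] = res.scenarios[0] if res.scenarios else Scenario(
            orders[node_key(node.parent_node)], orders[key]
        )

    return LabeledTree(
        tree=tree, orders=orders, branch_events=branch_events,
        total_cost=total_cost, ties=ties, unresolved=unresolved, pruned=pruned,
    )


# ---------------------------------------------------------------------------
# Synapomorphies

def describe_event(ev: Event, child: GeneOrder) -> str:
    """Human-readable account of the derived arrangement an event creates."""
    seg = [t.lstrip("-") for t in ev.genes]
    labels = [g.lstrip("-") for g in child.labels]
    try:
        i = next(
            p for p in range(len(labels) - len(seg) + 1)
            if labels[p : p + len(seg)] == seg
        )
    except StopIteration:
        # a tdrl re-sorts its segment: locate by content instead
        i = min(p for p, g in enumerate(labels) if g in set(seg))
    left = labels[i - 1] if i > 0 else labels[-1]
    j = i + len(seg)
    right = labels[j] if j < len(labels) else labels[0]
    what = ",".join(seg)
    if ev.kind == "i":
        return f"inversion of {what} (now between {left} and {right})"
    if ev.kind == "t":
        return f"transposition of {what}, now between {left} and {right}"
    if ev.kind == "iT":
        return f"inverse transposition of {what}, now between {left} and {right}"
    if ev.kind == "tdrl":
        kf = ",".join(t.lstrip("-") for t in ev.keep_first)
        return (f"tandem duplication–random loss over {what}: copy-one keeps "
                f"{kf}; segment now reads between {left} and {right}")
    return f"{ev.kind} of {what}"


def synapomorphies(
    ltree: LabeledTree, clade: Iterable[str]
) -> SynapomorphyReport:
    """Events on a clade's stem branch: its shared derived rearrangements."""
    clade = tuple(sorted(clade))
    target = set(clade)
    node = None
    for n in ltree.tree.preorder_node_iter():
        leaves = {lf.taxon.label for lf in n.leaf_iter()}
        if leaves == target:
            node = n
            break
    if node is None:
        raise ValueError(f"clade {clade} is not monophyletic in the tree")
    if node.parent_node is None:
        raise ValueError("the full tip set has no stem branch")
    key = node_key(node)
    scenario = ltree.branch_events.get(key)
    events = scenario.events if scenario else []
    child_order = ltree.orders[key]
    descriptions = [describe_event(ev, child_order) for ev in events]
    return SynapomorphyReport(
        clade=clade, events=list(events), descriptions=descriptions,
        derived_order=child_order,
    )
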