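"""Most-parsimonious rearrangement scenarios between gene orders.

Uses the bundled reference arrangements to recompute the stem scenario
separating the aculiferan ancestral order from the solenogaster ancestral
order, per conserved block: three events (two transpositions and one
tandem-duplication–random-loss) rearrange blocks 1–2, and two more events
rearrange block 3's KARNI tRNA cluster.
"""

from mitorder import GeneOrder, infer_scenario, reference_orders
from mitorder.vocab import ID_GENE

refs = reference_orders()
acu = refs["aculifera_ancestor"]
sol = refs["solenogastres_ancestor"]

BLOCK3 = {"cox3", "K", "A", "R", "N", "I", "nad3", "S1", "nad2"}
ALL = {ID_GENE[abs(g)] for g in acu.genes}


def restrict(order, keep, name):
    genes = tuple(g for g in order.genes if ID_GENE[abs(g)] in keep)
    return GeneOrder(name, genes, complete=False)


for label, keep in [("blocks 1+2", ALL - BLOCK3), ("block 3", BLOCK3 | {"cox1"})]:
    res = infer_scenario(restrict(acu, keep, "aculiferan"),
                         restrict(sol, keep, "solenogaster"), max_events=4)
    print(f"{label}: minimum {res.cost} events "
          f"({len(res.scenarios)} co-optimal scenarios)")
    best = res.scenarios[0]
    for step, ev in enumerate(best.events, 1):
        operands = ",".join(ev.genes)
        extra = ""
        if ev.kind in ("t", "iT"):
            extra = f" -> after {ev.after}"
        if ev.kind == "tdrl":
            extra = f" (keep-first: {','.join(ev.keep_first)})"
        print(f"  {step}. {ev.kind}: {operands}{extra}")
    assert best.replays()
    print()

# the three blocks 1+2 events are the solenogaster synapomorphies: trnD
# moves between atp8 and atp6, a tdrl leaves trnT+trnP adjacent to atp6,
# and trnL1 moves next to trnE (completing the MCYWQGL1E tRNA block)
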