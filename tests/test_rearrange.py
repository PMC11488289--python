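"""Rearrangement events, scenario inference, and the exhaustive oracle."""

import numpy as np
import pytest

from mitorder.gene_order import GeneOrder, reference_orders
from mitorder.rearrange import (
    Event,
    apply_event,
    bfs_oracle,
    detect_single_events,
    infer_scenario,
)
from mitorder.synthetic import random_event
from mitorder import vocab

L = {i: vocab.ID_GENE[i] for i in range(1, 11)}


def order(*genes):
    return GeneOrder("o", tuple(genes))


def labels(*genes):
    return tuple(("-" if g < 0 else "") + L[abs(g)] for g in genes)


class TestApplyEvent:
    def test_inversion_reverses_and_flips(self):
        o = order(1, 2, 3, 4)
        ev = Event("i", labels(2, 3))
        assert apply_event(o, ev).genes == (1, -3, -2, 4)

    def test_tdrl_definition_by_hand(self):
        # segment 1,2,3,4 keep-first {1,3}, keep-second {2,4} -> 1,3,2,4
        o = order(5, 1, 2, 3, 4)
        ev = Event("tdrl", labels(1, 2, 3, 4), keep_first=labels(1, 3))
        assert apply_event(o, ev).genes == (5, 1, 3, 2, 4)

    def test_transposition_to_original_position_is_identity(self):
        o = order(1, 2, 3, 4)
        ev = Event("t", labels(3,), after=labels(2)[0])
        assert apply_event(o, ev).genes == o.genes

    def test_inverse_transposition(self):
        o = order(1, 2, 3, 4)
        ev = Event("iT", labels(2,), after=labels(3)[0])
        assert apply_event(o, ev).genes == (1, 3, -2, 4)

    def test_signs_kept_by_transposition(self):
        o = order(1, -2, 3, 4)
        ev = Event("t", labels(-2,), after=labels(3)[0])
        assert apply_event(o, ev).genes == (1, 3, -2, 4)

    def test_duplication_flags_order(self):
        o = order(1, 2, 3)
        dup = apply_event(o, Event("dupl", labels(2,)))
        assert dup.genes == (1, 2, 2, 3) and dup.has_duplication

    def test_non_contiguous_operand_errors(self):
        o = order(1, 2, 3, 4)
        with pytest.raises(ValueError, match="contiguous"):
            apply_event(o, Event("i", labels(2, 4)))


class TestDetectSingleEvents:
    def test_identity_has_no_events(self):
        assert detect_single_events((1, 2, 3)) == []

    @pytest.mark.parametrize("state,kinds", [
        ((1, -3, -2, 4), {"i"}),
        ((1, 3, 2, 4), {"t", "tdrl"}),      # block swap = t; also a 2-split tdrl
        ((1, 3, -2, 4), {"iT"}),
        ((1, 3, 2, 4, 5), {"t", "tdrl"}),
    ])
    def test_kind_signatures(self, state, kinds):
        evs = detect_single_events(state)
        assert {e[0] for e in evs} == kinds

    def test_tdrl_value_split_detected(self):
        # interleaved ascending runs 2,3 / 4,5 sort by one tdrl, not by t/i/iT
        evs = detect_single_events((1, 4, 2, 5, 3, 6))
        assert {e[0] for e in evs} == {"tdrl"}
        (ev,) = evs
        assert ev[3] == (2, 3)  # keep-first = values <= theta, in window order


class TestInferScenario:
    def test_identical_orders_cost_zero(self):
        o = order(1, 2, 3, 4, 5)
        res = infer_scenario(o, o)
        assert res.cost == 0 and res.scenarios[0].events == []

    def test_every_scenario_replays(self):
        src = order(1, 2, 3, 4, 5, 6, 7)
        tgt = order(1, -5, -4, 7, 2, 3, 6)
        res = infer_scenario(src, tgt, max_events=3)
        assert res.cost is not None
        for sc in res.scenarios:
            assert sc.replays()

    def test_exceeds_bound_reported_explicitly(self):
        rng = np.random.default_rng(5)
        src = order(*range(1, 11))
        cur = src
        for _ in range(4):
            cur = apply_event(cur, random_event(cur.genes, rng))
        res = infer_scenario(src, cur, max_events=1)
        if res.cost is None:
            assert res.exceeded and res.scenarios == []
        else:  # events can collapse; then the scenario must replay
            assert res.cost <= 1

    def test_unequal_content_and_duplication_rejected(self):
        a, b = order(1, 2, 3), order(1, 2, 4)
        with pytest.raises(ValueError, match="unequal"):
            infer_scenario(a, b)
        dup = GeneOrder("d", (1, 2, 2, 3), has_duplication=True)
        with pytest.raises(ValueError, match="duplication"):
            infer_scenario(dup, dup)

    def test_cost_ties_ordered_by_kind_priority(self):
        # 1,3,2,4 is solvable by t and by tdrl: t must sort first
        res = infer_scenario(order(1, 2, 3, 4), order(1, 3, 2, 4))
        kinds = [sc.events[0].kind for sc in res.scenarios]
        assert kinds == sorted(kinds, key=lambda k: {"i": 0, "t": 1, "iT": 2,
                                                     "tdrl": 3}[k])

    def test_directional_asymmetry_of_tdrl(self):
        # a tdrl sorts 2,4,3,5 forward in one event; the reverse direction
        # needs a transposition too, but costs can differ in general
        src = order(1, 2, 4, 3, 5)
        tgt = order(1, 2, 3, 4, 5)
        fwd = infer_scenario(src, tgt)
        assert fwd.cost == 1
        kinds = {sc.events[0].kind for sc in fwd.scenarios}
        assert "tdrl" in kinds


class TestReferenceStemScenarios:
    """Stem scenarios recomputable from the bundled reference arrangements."""

    @staticmethod
    def restrict(order_, keep, oid):
        genes = tuple(
            g for g in order_.genes if vocab.ID_GENE[abs(g)] in keep
        )
        return GeneOrder(oid, genes, complete=False)

    BLOCK3 = {"cox3", "K", "A", "R", "N", "I", "nad3", "S1", "nad2"}

    def test_solenogaster_stem_blocks12_three_events(self):
        refs = reference_orders()
        keep = {vocab.ID_GENE[abs(g)]
                for g in refs["aculifera_ancestor"].genes} - self.BLOCK3
        src = self.restrict(refs["aculifera_ancestor"], keep, "a")
        tgt = self.restrict(refs["solenogastres_ancestor"], keep, "s")
        res = infer_scenario(src, tgt, max_events=4)
        assert res.cost == 3
        # the canonical scenario is among the co-optimal set: a transposition
        # of trnD, a tdrl leaving T,P adjacent to atp6, a transposition of L1
        def signature(sc):
            return tuple(
                (e.kind, frozenset(x.lstrip("-") for x in e.genes))
                for e in sorted(sc.events, key=lambda e: e.kind)
            )
        wanted_d = ("t", frozenset({"D"}))
        wanted_l1 = ("t", frozenset({"L1"}))
        found = any(
            wanted_d in signature(sc) and wanted_l1 in signature(sc)
            and any(e.kind == "tdrl" and {"T", "P"} <=
                    {x.lstrip("-") for x in e.keep_first or e.genes}
                    for e in sc.events)
            for sc in res.scenarios
        )
        assert found

    def test_solenogaster_stem_block3_two_events(self):
        refs = reference_orders()
        keep = self.BLOCK3 | {"cox1"}
        src = self.restrict(refs["aculifera_ancestor"], keep, "a")
        tgt = self.restrict(refs["solenogastres_ancestor"], keep, "s")
        assert infer_scenario(src, tgt, max_events=4).cost == 2

    def test_caudofoveate_stem_block_scenarios(self):
        refs = reference_orders()
        all_labels = {vocab.ID_GENE[abs(g)]
                      for g in refs["aculifera_ancestor"].genes}
        keep2 = all_labels - self.BLOCK3 - {"E"}
        src = self.restrict(refs["aculifera_ancestor"], keep2, "a")
        tgt = self.restrict(refs["caudofoveata_ancestor"], keep2, "c")
        assert infer_scenario(src, tgt, max_events=4).cost == 2
        keep3 = self.BLOCK3 | {"cox1", "E"}
        src = self.restrict(refs["aculifera_ancestor"], keep3, "a")
        tgt = self.restrict(refs["caudofoveata_ancestor"], keep3, "c")
        res = infer_scenario(src, tgt, max_events=4)
        assert res.cost == 2
        # the reversal of trnE is part of some co-optimal scenario
        assert any(
            any(e.kind == "i" and [x.lstrip("-") for x in e.genes] == ["E"]
                for e in sc.events)
            for sc in res.scenarios
        )


class TestOracle:
    def test_single_event_pairs_cost_one(self):
        rng = np.random.default_rng(3)
        src = order(*range(1, 8))
        for _ in range(20):
            ev = random_event(src.genes, rng)
            tgt = apply_event(src, ev)
            assert bfs_oracle(src, tgt, max_events=2) == 1

    def test_two_disjoint_inversions_cost_two(self):
        src = order(1, 2, 3, 4, 5)
        tgt = order(1, -2, 3, -5, -4)
        assert bfs_oracle(src, tgt, max_events=2) == 2

    def test_oversized_instance_rejected(self):
        src = order(*range(1, 12))
        with pytest.raises(ValueError, match="smaller"):
            bfs_oracle(src, src, max_events=3)

    def test_oracle_matches_inference_on_random_instances(self):
        rng = np.random.default_rng(11)
        for trial in range(40):
            n = int(rng.integers(5, 9))
            signs = rng.choice([1, -1], size=n)
            genes = (1,) + tuple(int(s) * (i + 1) for i, s in
                                 zip(range(1, n), signs[1:]))
            src = GeneOrder("s", genes)
            cur = src
            for _ in range(int(rng.integers(0, 3))):
                cur = apply_event(cur, random_event(cur.genes, rng))
            res = infer_scenario(src, cur, max_events=2)
            assert res.cost == bfs_oracle(src, cur, max_events=2)
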