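"""CTP/ITP/parallel reduction, the fixed-point loop, logs, and expansion."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petrimet import (
    ExpansionError,
    InvalidCandidateError,
    InvariantVector,
    PetriNet,
    ReductionLog,
    apply_ctp,
    apply_itp,
    coverage,
    expand_t_invariant,
    find_ctps,
    find_itps,
    find_parallel,
    is_t_invariant,
    merge_parallel,
    minimal_t_invariants,
    reduce_net,
)
from petrimet.synthetic import SynthConfig, random_cti_net

from conftest import chain_net


class TestFindCTPs:
    def test_chain_place_found(self):
        net = chain_net(1)  # IN -> m0 -> R0 -> m1 -> OUT
        assert find_ctps(net) == [("IN", "m0", "R0"), ("R0", "m1", "OUT")]

    def test_fig1_has_none(self, fig1):
        # p1 has two pre-transitions; p2 fits the wiring but carries weight 2
        assert find_ctps(fig1) == []
        assert ("t1", "p2", "t2") in find_ctps(fig1, strict_weights=False)

    def test_place_with_two_post_transitions_excluded(self, fig5):
        assert find_ctps(fig5) == []


class TestApplyCTP:
    def test_chain_merge_and_naming(self):
        net = chain_net(1)
        net2, events = apply_ctp(net, ("IN", "m0", "R0"))
        assert events[0].kind == "CTP"
        assert events[0].removed == ("m0", "R0")
        assert "ctp(IN + R0)" in net2.transitions
        assert net2.arcs == {("ctp(IN + R0)", "m1"): 1, ("m1", "OUT"): 1}

    def test_paper_style_naming(self):
        net = PetriNet(
            places={"86", "87", "88"},
            transitions={"E151", "E152"},
            arcs={
                ("86", "E151"): 1, ("E151", "87"): 1,
                ("87", "E152"): 1, ("E152", "88"): 1,
            },
        )
        net2, events = apply_ctp(net, ("E151", "87", "E152"))
        assert events[0].survivor == "ctp(E151 + E152)"
        assert "87" not in net2.places and "E152" not in net2.transitions
        assert net2.arcs == {("86", "ctp(E151 + E152)"): 1, ("ctp(E151 + E152)", "88"): 1}

    def test_mutually_reversible_pair_cancels_completely(self):
        # a and b invert each other on every other place: the merged
        # transition loses all arcs and is cleaned up
        net = PetriNet(
            places={"x", "c"},
            transitions={"a", "b"},
            arcs={
                ("x", "a"): 1, ("a", "c"): 1,
                ("c", "b"): 1, ("b", "x"): 1,
            },
        )
        net2, events = apply_ctp(net, ("a", "c", "b"))
        kinds = [e.kind for e in events]
        assert kinds == ["CTP", "CLEANUP"]
        assert net2.transitions == set()
        assert net2.places == set()  # x lost all arcs too

    def test_stale_candidate_raises(self):
        net = chain_net(1)
        net2, _ = apply_ctp(net, ("IN", "m0", "R0"))
        with pytest.raises(InvalidCandidateError):
            apply_ctp(net2, ("IN", "m0", "R0"))


class TestFindITPs:
    def test_fig5_reversible_pair(self, fig5):
        assert find_itps(fig5) == [("t2", "t3", "p1", "p2")]

    def test_weight_two_pair_excluded(self):
        net = PetriNet(
            places={"p", "q"},
            transitions={"f", "g"},
            arcs={("p", "f"): 2, ("f", "q"): 2, ("q", "g"): 1, ("g", "p"): 1},
        )
        assert find_itps(net) == []

    def test_boundary_special_case(self):
        # an external metabolite with dedicated input and output reactions
        net = PetriNet(
            places={"coa", "other"},
            transitions={"IN_coa", "OUT_coa", "use"},
            arcs={
                ("IN_coa", "coa"): 1, ("coa", "OUT_coa"): 1,
                ("other", "use"): 1,
            },
        )
        assert ("IN_coa", "OUT_coa", "coa", None) in find_itps(net)

    def test_shared_input_not_special_case(self):
        # the input also feeds another place, so deleting it is not allowed
        net = PetriNet(
            places={"x", "y"},
            transitions={"IN2", "OUTx"},
            arcs={("IN2", "x"): 1, ("IN2", "y"): 1, ("x", "OUTx"): 1},
        )
        assert find_itps(net) == []


class TestApplyITP:
    def test_paper_style_naming(self):
        # E24_f/E24_b link metabolites 76 and 50; the forward substrate
        # survives under the merged name
        net = PetriNet(
            places={"76", "50"},
            transitions={"E24_f", "E24_b", "mk", "use"},
            arcs={
                ("76", "E24_f"): 1, ("E24_f", "50"): 1,
                ("50", "E24_b"): 1, ("E24_b", "76"): 1,
                ("mk", "76"): 1, ("50", "use"): 1,
            },
        )
        quad = ("E24_f", "E24_b", "76", "50")
        assert quad in find_itps(net)
        net2, events = apply_itp(net, quad)
        assert events[0].survivor == "itp(76 + 50)"
        assert net2.transitions == {"mk", "use"}
        assert net2.arcs == {("mk", "itp(76 + 50)"): 1, ("itp(76 + 50)", "use"): 1}

    def test_fig5_merge_sums_parallel_arc_weights(self, fig5):
        net2, events = apply_itp(fig5, ("t2", "t3", "p1", "p2"))
        merged = events[0].survivor
        assert merged == "itp(p1 + p2)"
        assert net2.arcs[("t1", merged)] == 2

    def test_marking_merges_additively(self, fig5):
        net = fig5.copy()
        net.initial_marking = {"p1": 2, "p2": 3}
        net2, _ = apply_itp(net, ("t2", "t3", "p1", "p2"))
        assert sum(net2.initial_marking.values()) == 5

    def test_duplicate_itp_over_same_places_removed(self):
        # two reversible pairs between p and q: reducing one leaves the other
        # as self-loops, which disappear
        net = PetriNet(
            places={"p", "q"},
            transitions={"f1", "b1", "f2", "b2", "mk", "use"},
            arcs={
                ("p", "f1"): 1, ("f1", "q"): 1, ("q", "b1"): 1, ("b1", "p"): 1,
                ("p", "f2"): 1, ("f2", "q"): 1, ("q", "b2"): 1, ("b2", "p"): 1,
                ("mk", "p"): 1, ("q", "use"): 1,
            },
        )
        quad = find_itps(net)[0]
        net2, events = apply_itp(net, quad)
        assert net2.transitions == {"mk", "use"}
        assert any(e.kind == "CLEANUP" for e in events)


class TestParallelMerge:
    def test_unit_parallel_pair_merges(self):
        net = PetriNet(
            places={"p", "q"},
            transitions={"u", "v", "IN", "OUT"},
            arcs={
                ("IN", "p"): 1, ("p", "u"): 1, ("u", "q"): 1,
                ("p", "v"): 1, ("v", "q"): 1, ("q", "OUT"): 1,
            },
        )
        assert find_parallel(net) == [("u", "v")]
        net2, events = merge_parallel(net, ("u", "v"))
        assert events[0].survivor == "u"
        assert "v" not in net2.transitions

    def test_weight_mismatch_not_parallel(self):
        net = PetriNet(
            places={"p", "q"},
            transitions={"u", "v"},
            arcs={("p", "u"): 1, ("u", "q"): 1, ("p", "v"): 2, ("v", "q"): 2},
        )
        assert find_parallel(net) == []

    def test_extra_pre_place_not_parallel(self):
        net = PetriNet(
            places={"p", "q", "r"},
            transitions={"u", "v"},
            arcs={
                ("p", "u"): 1, ("u", "q"): 1,
                ("p", "v"): 1, ("r", "v"): 1, ("v", "q"): 1,
            },
        )
        assert find_parallel(net) == []


class TestReduceLoop:
    def test_fig5_one_itp_event(self, fig5):
        reduced, log = reduce_net(fig5)
        assert [e.kind for e in log.events] == ["ITP"]
        assert reduced.places == {"itp(p1 + p2)"}
        assert reduced.transitions == {"t1", "t4", "t5"}
        assert reduced.arcs[("t1", "itp(p1 + p2)")] == 2

    def test_fig1_unchanged(self, fig1):
        reduced, log = reduce_net(fig1)
        assert log.events == []
        assert reduced.arcs == fig1.arcs

    def test_chain_collapses_to_nothing(self):
        # every connecting place is a CTP; the end-to-end merge leaves one
        # input and one output transition on one place -- the boundary ITP
        # special case -- after which nothing remains
        reduced, log = reduce_net(chain_net(4))
        assert reduced.places == set() and reduced.transitions == set()
        assert [e.kind for e in log.events] == ["CTP"] * 4 + ["ITP"]

    def test_itp_preferred_over_simultaneous_ctp(self):
        # q is connected to the rest of the net only through the reversible
        # pair a/b, so (a, q, b) is a CTP that also forms an ITP
        net = PetriNet(
            places={"p", "q"},
            transitions={"a", "b", "mk", "use"},
            arcs={
                ("p", "a"): 1, ("a", "q"): 1, ("q", "b"): 1, ("b", "p"): 1,
                ("mk", "p"): 1, ("p", "use"): 1,
            },
        )
        assert ("a", "q", "b") in find_ctps(net)
        _, log = reduce_net(net)
        assert log.events[0].kind == "ITP"
        assert set(log.events[0].candidate[:2]) == {"a", "b"}

    def test_boundary_special_case_removed(self):
        net = PetriNet(
            places={"coa", "x"},
            transitions={"IN_coa", "OUT_coa", "IN_x", "OUT_x2", "OUT_x3"},
            arcs={
                ("IN_coa", "coa"): 1, ("coa", "OUT_coa"): 1,
                ("IN_x", "x"): 1, ("x", "OUT_x2"): 1, ("x", "OUT_x3"): 1,
            },
        )
        reduced, log = reduce_net(net)
        assert "coa" not in reduced.places
        assert any(
            e.kind == "ITP" and e.candidate[3] is None for e in log.events
        )

    def test_monotone_shrinkage(self, fig5):
        _, log = reduce_net(fig5)
        sizes = [len(n.places) + len(n.transitions) for n in log.nets()]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_log_replay_reproduces_reduced_net(self, seed):
        net = random_cti_net(SynthConfig(seed=seed, p_heavy=0.1))
        reduced, log = reduce_net(net)
        replayed = log.replay()
        assert replayed.places == reduced.places
        assert replayed.transitions == reduced.transitions
        assert replayed.arcs == reduced.arcs
        assert replayed.initial_marking == reduced.initial_marking

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_cti_preserved_and_expansion_sound(self, seed):
        net = random_cti_net(SynthConfig(seed=seed))
        assert coverage(net, minimal_t_invariants(net)).covered
        reduced, log = reduce_net(net)
        reduced_tis = minimal_t_invariants(reduced)
        if reduced.transitions:
            assert coverage(reduced, reduced_tis).covered
        for y in reduced_tis:
            assert is_t_invariant(net, expand_t_invariant(log, y))


class TestMergedNames:
    def test_nested_expression_tree(self):
        reduced, log = reduce_net(chain_net(2))
        # everything merged away, but the expression trees were recorded
        # along the way on intermediate survivors; rerun on a chain that
        # keeps its merged transition:
        net = PetriNet(
            places={"s", "m", "t"},
            transitions={"R1", "R2"},
            arcs={("s", "R1"): 1, ("R1", "m"): 1, ("m", "R2"): 1, ("R2", "t"): 2},
        )
        reduced, log = reduce_net(net)
        assert "ctp(R1 + R2)" in reduced.transitions
        expr = log.merged_names["ctp(R1 + R2)"]
        assert expr.render() == "ctp(R1 + R2)"
        assert expr.leaves() == ("R1", "R2")


class TestExpansion:
    def test_fig5_expansions_match_printed_tis(self, fig5):
        reduced, log = reduce_net(fig5)
        expanded = {
            expand_t_invariant(log, y).entries for y in minimal_t_invariants(reduced)
        }
        assert expanded == {
            (("t1", 1), ("t3", 1), ("t4", 2)),
            (("t1", 1), ("t2", 1), ("t5", 2)),
        }

    def test_ctp_only_expansion_copies_coefficients(self):
        net = chain_net(1)  # IN -> m0 -> R0 -> m1 -> OUT
        net2, events = apply_ctp(net, ("IN", "m0", "R0"))
        log = ReductionLog(original=net, events=list(events), final=net2)
        y_red = InvariantVector.from_dict(
            "transition", {"ctp(IN + R0)": 1, "OUT": 1}
        )
        assert is_t_invariant(net2, y_red)
        y = expand_t_invariant(log, y_red)
        assert dict(y.entries) == {"IN": 1, "R0": 1, "OUT": 1}

    def test_non_invariant_input_rejected(self, fig5):
        _, log = reduce_net(fig5)
        bogus = InvariantVector.from_dict("transition", {"t1": 1, "t4": 1})
        with pytest.raises(ExpansionError):
            expand_t_invariant(log, bogus)
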