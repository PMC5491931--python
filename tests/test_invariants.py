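"""Minimal invariant enumeration, classification, coverage, subnets."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petrimet import (
    CapExceededError,
    InvariantVector,
    PetriNet,
    brute_force_minimal_invariants,
    classify_all,
    classify_ti,
    coverage,
    detect_reversible_pairs,
    invariant_subnet,
    is_p_invariant,
    is_t_invariant,
    minimal_p_invariants,
    minimal_t_invariants,
)
from petrimet.invariants import (
    DimensionError,
    KindMismatchError,
    SubnetDisconnectedError,
    TooLargeError,
)
from petrimet.synthetic import SynthConfig, random_cti_net


def tiv(**coeffs) -> InvariantVector:
    return InvariantVector.from_dict("transition", coeffs)


class TestMembership:
    def test_fig1_printed_ti_is_invariant(self, fig1):
        assert is_t_invariant(fig1, tiv(t1=1, t2=1, t3=4))

    def test_fig1_wrong_coefficients_rejected(self, fig1):
        assert not is_t_invariant(fig1, tiv(t1=1, t2=1, t3=3))

    def test_zero_vector_is_not_an_invariant(self, fig1):
        assert not is_t_invariant(fig1, InvariantVector("transition", ()))

    def test_unknown_index_signals_dimension_error(self, fig1):
        with pytest.raises(DimensionError):
            is_t_invariant(fig1, tiv(t9=1))
        with pytest.raises(DimensionError):
            is_p_invariant(fig1, tiv(t1=1))  # wrong kind


class TestEnumeration:
    def test_fig1_has_exactly_the_printed_ti(self, fig1):
        tis = minimal_t_invariants(fig1)
        assert [dict(y.entries) for y in tis] == [{"t1": 1, "t2": 1, "t3": 4}]

    def test_fig1_has_no_place_invariants(self, fig1):
        assert minimal_p_invariants(fig1) == []

    def test_fig5_original_minimal_tis(self, fig5):
        # two boundary-to-boundary pathways, the reversible pair, and the
        # split pathway t1+t4+t5 (support-minimal: no invariant lives on a
        # strict subset of {t1,t4,t5})
        tis = {y.entries for y in minimal_t_invariants(fig5)}
        assert tis == {
            (("t1", 1), ("t3", 1), ("t4", 2)),
            (("t1", 1), ("t2", 1), ("t5", 2)),
            (("t2", 1), ("t3", 1)),
            (("t1", 1), ("t4", 1), ("t5", 1)),
        }

    def test_enumeration_cap_signals_cleanly(self):
        net = random_cti_net(SynthConfig(n_pathways=4, seed=3))
        with pytest.raises(CapExceededError):
            minimal_t_invariants(net, max_intermediate=1)

    def test_conservation_cycle_has_place_invariant(self):
        # closed two-place shuttle: total token count is conserved
        net = PetriNet(
            places={"a", "b"}, transitions={"f", "g"},
            arcs={("a", "f"): 1, ("f", "b"): 1, ("b", "g"): 1, ("g", "a"): 1},
        )
        pis = minimal_p_invariants(net)
        assert [dict(x.entries) for x in pis] == [{"a": 1, "b": 1}]


class TestBruteForceOracle:
    def test_fig1_bound_four(self, fig1):
        assert [dict(y.entries) for y in brute_force_minimal_invariants(fig1, 4)] == [
            {"t1": 1, "t2": 1, "t3": 4}
        ]

    def test_bound_too_small_misses_invariant(self, fig1):
        # t3 needs coefficient 4; a bound of 3 cannot reach it
        assert brute_force_minimal_invariants(fig1, 3) == []

    def test_guard_rejects_large_nets(self):
        net = random_cti_net(SynthConfig(n_pathways=3, seed=0))
        assert len(net.transitions) > 8
        with pytest.raises(TooLargeError):
            brute_force_minimal_invariants(net, 2)

    def test_agrees_with_enumeration_on_fixtures(self, fig1, fig5):
        for net, bound in ((fig1, 4), (fig5, 2)):
            assert minimal_t_invariants(net) == brute_force_minimal_invariants(net, bound)
            assert minimal_p_invariants(net) == brute_force_minimal_invariants(
                net, 4, kind="place"
            )

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_oracle_equivalence_on_small_random_nets(self, seed):
        cfg = SynthConfig(
            n_pathways=1, chain_length=(1, 3), p_reversible=0.4, seed=seed
        )
        net = random_cti_net(cfg)
        if len(net.transitions) > 6:
            return
        assert minimal_t_invariants(net) == brute_force_minimal_invariants(net, 3)


class TestInvariantProperties:
    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_soundness_minimality_gcd_closure(self, seed):
        from math import gcd

        net = random_cti_net(SynthConfig(seed=seed, p_heavy=0.2))
        tis = minimal_t_invariants(net)
        assert len({y.entries for y in tis}) == len(tis)
        for y in tis:
            assert is_t_invariant(net, y)
            g = 0
            for _, c in y.entries:
                assert c > 0
                g = gcd(g, c)
            assert g == 1
        for y in tis:
            assert not any(z.support < y.support for z in tis if z is not y)
        if len(tis) >= 2:
            combo = {}
            for y in tis[:3]:
                for t, c in y.entries:
                    combo[t] = combo.get(t, 0) + 2 * c
            assert is_t_invariant(net, InvariantVector.from_dict("transition", combo))


class TestClassification:
    def test_fig1_ti_is_inout(self, fig1):
        assert classify_ti(fig1, tiv(t1=1, t2=1, t3=4)) == "INOUT"

    def test_fig5_reversible_pair_is_trivial(self, fig5):
        assert ("t2", "t3") in detect_reversible_pairs(fig5)
        assert classify_ti(fig5, tiv(t2=1, t3=1)) == "trivial"

    def test_pure_cycle_is_cyc(self):
        # three-step cycle: unambiguous (a two-step cycle is structurally a
        # split reversible pair and classifies as trivial unless overridden)
        net = PetriNet(
            places={"p", "q", "r"}, transitions={"a", "b", "c"},
            arcs={
                ("a", "p"): 1, ("p", "b"): 1, ("b", "q"): 1,
                ("q", "c"): 1, ("c", "r"): 1, ("r", "a"): 1,
            },
        )
        assert classify_ti(net, tiv(a=1, b=1, c=1)) == "CYC"

    def test_two_cycle_with_overriding_declaration_is_cyc(self):
        net = PetriNet(
            places={"p", "q"}, transitions={"a", "b"},
            arcs={("a", "p"): 1, ("p", "b"): 1, ("b", "q"): 1, ("q", "a"): 1},
        )
        assert classify_ti(net, tiv(a=1, b=1)) == "trivial"  # detected pair
        assert classify_ti(net, tiv(a=1, b=1), reversible_pairs=set()) == "CYC"

    def test_suffix_convention_declares_pair(self):
        net = PetriNet(
            places={"x", "y", "z"},
            transitions={"E24_f", "E24_b", "mk", "rm"},
            arcs={
                ("mk", "x"): 1, ("x", "E24_f"): 1, ("E24_f", "y"): 1,
                ("y", "E24_b"): 1, ("E24_b", "x"): 1, ("y", "rm"): 1,
            },
        )
        assert ("E24_b", "E24_f") in detect_reversible_pairs(net)
        assert classify_ti(net, tiv(E24_f=1, E24_b=1)) == "trivial"

    def test_in_class_for_internal_consumption(self):
        # an input feeds a 2:1 condensation loop: no output transition needed
        net_in = PetriNet(
            places={"p", "q"}, transitions={"IN_p", "sw", "ws"},
            arcs={
                ("IN_p", "p"): 1, ("p", "sw"): 2, ("sw", "q"): 1,
                ("q", "ws"): 1, ("ws", "p"): 1,
            },
        )
        y = tiv(IN_p=1, sw=1, ws=1)
        assert is_t_invariant(net_in, y)
        assert classify_ti(net_in, y) == "IN"

    def test_class_count_table(self, fig5):
        counts = classify_all(fig5, minimal_t_invariants(fig5))
        assert counts["All"] == 4
        assert counts["trivial"] == 1
        assert counts["INOUT"] == 3
        assert counts["IN"] == counts["OUT"] == counts["CYC"] == 0


class TestCoverage:
    def test_fig1_is_cti(self, fig1):
        rep = coverage(fig1, minimal_t_invariants(fig1))
        assert rep.covered and rep.uncovered == frozenset()

    def test_fig1_empty_pi_set_uncovers_all_places(self, fig1):
        rep = coverage(fig1, [], kind="place")
        assert not rep.covered
        assert rep.uncovered == {"p1", "p2"}

    def test_fig5_covered_by_its_tis(self, fig5):
        assert coverage(fig5, minimal_t_invariants(fig5)).covered

    def test_mixed_kinds_rejected(self, fig1):
        with pytest.raises(KindMismatchError):
            coverage(fig1, [tiv(t1=1), InvariantVector.from_dict("place", {"p1": 1})])

    def test_empty_set_requires_kind(self, fig1):
        with pytest.raises(KindMismatchError):
            coverage(fig1, [])


class TestInvariantSubnet:
    def test_fig1_ti_subnet_is_whole_net(self, fig1):
        sub = invariant_subnet(fig1, tiv(t1=1, t2=1, t3=4))
        assert sub.places == fig1.places
        assert sub.transitions == fig1.transitions
        assert sub.arcs == fig1.arcs

    def test_reduced_fig5_ti_subnet(self, fig5):
        from petrimet import minimal_t_invariants as mti, reduce_net

        reduced, _ = reduce_net(fig5)
        y = next(y for y in mti(reduced) if "t4" in y.support)
        sub = invariant_subnet(reduced, y)
        assert sub.transitions == {"t1", "t4"}
        assert sub.places == {"itp(p1 + p2)"}

    def test_disconnected_ti_subnet_raises(self):
        # two disjoint two-place cycles; the union vector is a TI whose
        # induced subnet falls apart
        net = PetriNet(
            places={"pA", "qA", "pB", "qB"},
            transitions={"fA", "gA", "fB", "gB"},
            arcs={
                ("pA", "fA"): 1, ("fA", "qA"): 1, ("qA", "gA"): 1, ("gA", "pA"): 1,
                ("pB", "fB"): 1, ("fB", "qB"): 1, ("qB", "gB"): 1, ("gB", "pB"): 1,
            },
        )
        y = tiv(fA=1, gA=1, fB=1, gB=1)
        assert is_t_invariant(net, y)
        with pytest.raises(SubnetDisconnectedError):
            invariant_subnet(net, y)
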