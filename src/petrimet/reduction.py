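"""CTI-preserving structural network reduction and invariant expansion.

Three local patterns are merged, each chosen because it leaves the set of
minimal transition invariants reconstructible and preserves coverage by TIs:

* **CTP** (common transition pair): a connecting place with exactly one
  pre-transition t_i and one post-transition t_j.  t_j and the place are
  deleted; t_i absorbs t_j's remaining arcs and is renamed ``ctp(t_i + t_j)``.
* **ITP** (invariant transition pair): a forward/backward transition pair
  reciprocally connecting two places.  Both transitions and one place are
  deleted; the surviving place absorbs the other's arcs and marking and is
  renamed ``itp(p_i + p_j)``.  A place wired only to one input and one output
  transition is the boundary special case of an ITP.
* **PARALLEL**: two unit-weight transitions with identical single pre- and
  post-places collapse to one.

Merging is exact incidence arithmetic: the merged transition's column is the
sum of its constituents' columns (resp. the merged place's row the sum of the
rows), with opposite-direction arcs to the same neighbor netted into a single
arc.  Full cancellation of a merged reversible pair and the removal of
transitions left as pure self-loops on a merged place fall out of this rule;
vertices left without arcs are removed and logged as CLEANUP events.

The recursive loop applies the first CTP in canonical order, else the first
ITP, else a parallel merge, restarting the CTP search after every event; a
candidate that is simultaneously a CTP and an ITP is reduced as the ITP.
Every event strictly shrinks |P| + |T|, so the loop terminates.  The ordered
event log replays deterministically and supports mapping TIs of the reduced
net back to TIs of the original net (:func:`expand_t_invariant`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

from .core import Marking, PetriNet, PetriNetError
from .invariants import InvariantVector, is_t_invariant

__all__ = [
    "InvalidCandidateError",
    "ExpansionError",
    "MergedName",
    "ReductionEvent",
    "ReductionLog",
    "find_ctps",
    "apply_ctp",
    "find_itps",
    "apply_itp",
    "find_parallel",
    "merge_parallel",
    "reduce_net",
    "expand_t_invariant",
]


class InvalidCandidateError(PetriNetError, ValueError):
    """The CTP/ITP/parallel candidate is no longer valid in the net."""


class ExpansionError(PetriNetError, RuntimeError):
    """A reduced invariant could not be balanced back onto the original net."""


@dataclass(frozen=True)
class MergedName:
    """Expression tree over original vertex ids, e.g. ``ctp(E151 + E152)``.

    Leaves are original ids; nesting follows the reduction history, as in
    ``ctp(ctp(E42 + E43) + ctp(E44 + ctp(E61_119 + E61_80)))``.
    """

    op: str  # "ctp" | "itp"
    parts: tuple[Union["MergedName", str], ...]

    def render(self) -> str:
        inner = " + ".join(
            p.render() if isinstance(p, MergedName) else p for p in self.parts
        )
        return f"{self.op}({inner})"

    def leaves(self) -> tuple[str, ...]:
        out: list[str] = []
        for p in self.parts:
            out.extend(p.leaves() if isinstance(p, MergedName) else (p,))
        return tuple(out)


Candidate = tuple  # CTP (t_i, p_c, t_j); ITP (t_i, t_j, p_i, p_j|None); PARALLEL (u, v)


@dataclass(frozen=True)
class ReductionEvent:
    """One reduction step: what was removed, what survived, under what name."""

    step: int
    kind: str  # "CTP" | "ITP" | "PARALLEL" | "CLEANUP"
    candidate: Candidate | None
    removed: tuple[str, ...]
    survivor_before: str | None = None
    survivor: str | None = None


@dataclass
class ReductionLog:
    """Ordered reduction events plus the original and final nets.

    Replaying the events on the original net reproduces the final net
    exactly; ``merged_names`` maps surviving merged ids to their expression
    trees over original ids.
    """

    original: PetriNet
    events: list[ReductionEvent] = field(default_factory=list)
    final: PetriNet | None = None
    merged_names: dict[str, MergedName] = field(default_factory=dict)

    def replay(self, net: PetriNet | None = None) -> PetriNet:
        work = (net or self.original).copy()
        for ev in self.events:
            _replay_event(work, ev)
        return work

    def nets(self) -> list[PetriNet]:
        """The net before each event, followed by the final net."""
        out = [self.original.copy()]
        for ev in self.events:
            nxt = out[-1].copy()
            _replay_event(nxt, ev)
            out.append(nxt)
        return out

    def to_rows(self) -> list[dict[str, str]]:
        return [
            {
                "step": str(ev.step),
                "kind": ev.kind,
                "removed": "+".join(ev.removed),
                "survivor_before": ev.survivor_before or "",
                "survivor": ev.survivor or "",
            }
            for ev in self.events
        ]


# ---------------------------------------------------------------------------
# low-level net surgery (mutating; callers pass working copies)


def _remove_vertex(net: PetriNet, v: str) -> None:
    net.places.discard(v)
    net.transitions.discard(v)
    net.arcs = {k: w for k, w in net.arcs.items() if v not in k}
    net.initial_marking.pop(v, None)
    net.capacities.pop(v, None)
    net.logical_groups = {c: g for c, g in net.logical_groups.items() if g != v}


def _rename_vertex(net: PetriNet, old: str, new: str) -> None:
    if old in net.places:
        net.places.remove(old)
        net.places.add(new)
    else:
        net.transitions.remove(old)
        net.transitions.add(new)
    net.arcs = {
        (new if u == old else u, new if v == old else v): w
        for (u, v), w in net.arcs.items()
    }
    if old in net.initial_marking:
        net.initial_marking[new] = net.initial_marking.pop(old)
    if old in net.capacities:
        net.capacities[new] = net.capacities.pop(old)
    net.logical_groups = {
        c: (new if g == old else g) for c, g in net.logical_groups.items()
    }


def _set_net_arc(net: PetriNet, a: str, b: str, delta: int) -> None:
    """Install the netted effect between two vertices: a single arc a->b of
    weight delta (>0), b->a of -delta (<0), or no arc (0)."""
    net.arcs.pop((a, b), None)
    net.arcs.pop((b, a), None)
    if delta > 0:
        net.arcs[(a, b)] = delta
    elif delta < 0:
        net.arcs[(b, a)] = -delta


def _merge_ctp(net: PetriNet, t_i: str, p_c: str, t_j: str) -> str:
    """Delete p_c and t_j; fold t_j's column into t_i's; rename t_i."""
    _remove_vertex(net, p_c)
    neighbors = {
        p
        for p in net.places
        if (p, t_i) in net.arcs
        or (t_i, p) in net.arcs
        or (p, t_j) in net.arcs
        or (t_j, p) in net.arcs
    }
    for p in neighbors:
        delta = (
            net.weight(t_i, p)
            + net.weight(t_j, p)
            - net.weight(p, t_i)
            - net.weight(p, t_j)
        )
        net.arcs.pop((p, t_j), None)
        net.arcs.pop((t_j, p), None)
        _set_net_arc(net, t_i, p, delta)
    _remove_vertex(net, t_j)
    new_name = f"ctp({t_i} + {t_j})"
    _rename_vertex(net, t_i, new_name)
    return new_name


def _merge_itp(net: PetriNet, t_i: str, t_j: str, p_i: str, p_j: str) -> str:
    """Delete t_i, t_j and p_j; fold p_j's row into p_i's; rename p_i."""
    _remove_vertex(net, t_i)
    _remove_vertex(net, t_j)
    neighbors = {
        t
        for t in net.transitions
        if (t, p_i) in net.arcs
        or (p_i, t) in net.arcs
        or (t, p_j) in net.arcs
        or (p_j, t) in net.arcs
    }
    for t in neighbors:
        delta = (
            net.weight(t, p_i)
            + net.weight(t, p_j)
            - net.weight(p_i, t)
            - net.weight(p_j, t)
        )
        net.arcs.pop((t, p_j), None)
        net.arcs.pop((p_j, t), None)
        _set_net_arc(net, t, p_i, delta)
    # tokens add; capacities add when both are bounded, else unbounded
    net.initial_marking[p_i] = net.initial_marking.get(p_i, 0) + net.initial_marking.get(
        p_j, 0
    )
    if p_i in net.capacities and p_j in net.capacities:
        net.capacities[p_i] = net.capacities[p_i] + net.capacities[p_j]
    else:
        net.capacities.pop(p_i, None)
    _remove_vertex(net, p_j)
    new_name = f"itp({p_i} + {p_j})"
    _rename_vertex(net, p_i, new_name)
    return new_name


def _isolated(net: PetriNet) -> list[str]:
    used = {u for (u, _) in net.arcs} | {v for (_, v) in net.arcs}
    return sorted((net.places | net.transitions) - used)


def _replay_event(net: PetriNet, ev: ReductionEvent) -> None:
    if ev.kind == "CTP":
        t_i, p_c, t_j = ev.candidate  # type: ignore[misc]
        _merge_ctp(net, t_i, p_c, t_j)
    elif ev.kind == "ITP":
        t_i, t_j, p_i, p_j = ev.candidate  # type: ignore[misc]
        if p_j is None:
            for v in (t_i, t_j, p_i):
                _remove_vertex(net, v)
        else:
            _merge_itp(net, t_i, t_j, p_i, p_j)
    elif ev.kind == "PARALLEL":
        _, v = ev.candidate  # type: ignore[misc]
        _remove_vertex(net, v)
    elif ev.kind == "CLEANUP":
        for v in ev.removed:
            _remove_vertex(net, v)
    else:  # pragma: no cover
        raise ValueError(f"unknown event kind {ev.kind!r}")


# ---------------------------------------------------------------------------
# candidate search


def find_ctps(net: PetriNet, strict_weights: bool = True) -> list[tuple[str, str, str]]:
    """All CTP triples (t_i, p_c, t_j): p_c has exactly one pre-transition and
    one post-transition, t_i != t_j, and (by default) both arcs through p_c
    have weight 1.  Canonical lexicographic order."""
    out = []
    for p in net.sorted_places:
        pre = net.pre_set(p)
        post = net.post_set(p)
        if len(pre) != 1 or len(post) != 1:
            continue
        (t_i,) = pre
        (t_j,) = post
        if t_i == t_j:
            continue  # read arc / self-loop on the place
        if strict_weights and (net.weight(t_i, p) != 1 or net.weight(p, t_j) != 1):
            continue
        out.append((t_i, p, t_j))
    return sorted(out)


def _single_pre_post(net: PetriNet, t: str) -> tuple[str, str] | None:
    pre = net.pre_set(t)
    post = net.post_set(t)
    if len(pre) == 1 and len(post) == 1:
        (a,) = pre
        (b,) = post
        if a != b:
            return a, b
    return None


def find_itps(net: PetriNet) -> list[tuple[str, str, str, str | None]]:
    """All ITP quadruples (t_i, t_j, p_i, p_j): two transitions with exactly
    one pre- and one post-place each, wired reciprocally between p_i and p_j,
    all four arcs of weight 1 (p_i is t_i's pre-place; t_i is the smaller id).

    Includes the boundary special case -- a place wired only to one dedicated
    input and one dedicated output transition -- returned with p_j = None.
    """
    out: list[tuple[str, str, str, str | None]] = []
    shapes = {t: _single_pre_post(net, t) for t in net.transitions}
    for t_i in net.sorted_transitions:
        sh = shapes.get(t_i)
        if sh is None:
            continue
        p_i, p_j = sh
        for t_j in net.sorted_transitions:
            if t_j <= t_i or shapes.get(t_j) != (p_j, p_i):
                continue
            if (
                net.weight(p_i, t_i) == net.weight(t_i, p_j)
                == net.weight(p_j, t_j) == net.weight(t_j, p_i) == 1
            ):
                # orient a suffix-named pair forward-first, so the forward
                # substrate place survives the merge (E24_f/E24_b linking
                # 76 and 50 yields itp(76 + 50))
                if t_i.endswith("_b") and t_j == t_i[:-2] + "_f":
                    out.append((t_j, t_i, p_j, p_i))
                else:
                    out.append((t_i, t_j, p_i, p_j))
    for p in net.sorted_places:
        pre = net.pre_set(p)
        post = net.post_set(p)
        if len(pre) != 1 or len(post) != 1:
            continue
        (a,) = pre
        (b,) = post
        if a == b:
            continue
        if net.pre_set(a) or net.post_set(b):
            continue  # a must be an input, b an output transition
        if net.post_set(a) != {p} or net.pre_set(b) != {p}:
            continue  # dedicated boundary pair
        if net.weight(a, p) == net.weight(p, b) == 1:
            out.append((a, b, p, None))
    return sorted(out, key=lambda q: (q[0], q[1], q[2], q[3] or ""))


def find_parallel(net: PetriNet) -> list[tuple[str, str]]:
    """Pairs of transitions with identical single pre-place and single
    post-place and all arc weights 1; canonical order, smaller id first."""
    by_shape: dict[tuple[str, str], list[str]] = {}
    for t in net.sorted_transitions:
        sh = _single_pre_post(net, t)
        if sh is None:
            continue
        p, q = sh
        if net.weight(p, t) == net.weight(t, q) == 1:
            by_shape.setdefault(sh, []).append(t)
    out = []
    for group in by_shape.values():
        for i, u in enumerate(group):
            for v in group[i + 1 :]:
                out.append((u, v))
    return sorted(out)


# ---------------------------------------------------------------------------
# event application


def _cleanup_events(net: PetriNet, step: int) -> list[ReductionEvent]:
    events = []
    isolated = _isolated(net)
    if isolated:
        for v in isolated:
            _remove_vertex(net, v)
        events.append(
            ReductionEvent(step=step, kind="CLEANUP", candidate=None, removed=tuple(isolated))
        )
    return events


def apply_ctp(
    net: PetriNet,
    triple: tuple[str, str, str],
    start_step: int = 0,
    strict_weights: bool = True,
) -> tuple[PetriNet, list[ReductionEvent]]:
    """Apply one CTP merge, returning the new net and the logged events.

    The merge event may be followed by a CLEANUP event when the merged
    transition cancels completely (mutually reversible pair) or neighbors
    are left without arcs.
    """
    if triple not in find_ctps(net, strict_weights=strict_weights):
        raise InvalidCandidateError(f"not a current CTP: {triple}")
    t_i, p_c, t_j = triple
    work = net.copy()
    new_name = _merge_ctp(work, t_i, p_c, t_j)
    events = [
        ReductionEvent(
            step=start_step,
            kind="CTP",
            candidate=triple,
            removed=(p_c, t_j),
            survivor_before=t_i,
            survivor=new_name,
        )
    ]
    events += _cleanup_events(work, start_step + 1)
    return work, events


def apply_itp(
    net: PetriNet,
    quadruple: tuple[str, str, str, str | None],
    start_step: int = 0,
) -> tuple[PetriNet, list[ReductionEvent]]:
    """Apply one ITP merge (or the boundary special case), returning the new
    net and the logged events.  Transitions left as pure self-loops on the
    merged place (duplicate ITPs over the same place pair) disappear in the
    netting and are removed by the trailing CLEANUP event."""
    if quadruple not in find_itps(net):
        raise InvalidCandidateError(f"not a current ITP: {quadruple}")
    t_i, t_j, p_i, p_j = quadruple
    work = net.copy()
    if p_j is None:
        for v in (t_i, t_j, p_i):
            _remove_vertex(work, v)
        events = [
            ReductionEvent(
                step=start_step,
                kind="ITP",
                candidate=quadruple,
                removed=(t_i, t_j, p_i),
            )
        ]
    else:
        new_name = _merge_itp(work, t_i, t_j, p_i, p_j)
        events = [
            ReductionEvent(
                step=start_step,
                kind="ITP",
                candidate=quadruple,
                removed=(t_i, t_j, p_j),
                survivor_before=p_i,
                survivor=new_name,
            )
        ]
    events += _cleanup_events(work, start_step + 1)
    return work, events


def merge_parallel(
    net: PetriNet, pair: tuple[str, str], start_step: int = 0
) -> tuple[PetriNet, list[ReductionEvent]]:
    """Merge a parallel transition pair; the first (canonical) member
    survives under its own name."""
    if pair not in find_parallel(net):
        raise InvalidCandidateError(f"not a current parallel pair: {pair}")
    u, v = pair
    work = net.copy()
    _remove_vertex(work, v)
    events = [
        ReductionEvent(
            step=start_step,
            kind="PARALLEL",
            candidate=pair,
            removed=(v,),
            survivor_before=u,
            survivor=u,
        )
    ]
    events += _cleanup_events(work, start_step + 1)
    return work, events


# ---------------------------------------------------------------------------
# the reduction loop


def _expr(table: dict[str, MergedName], vid: str) -> Union[MergedName, str]:
    return table.get(vid, vid)


def reduce_net(
    net: PetriNet, strict_ctp_weights: bool = True
) -> tuple[PetriNet, ReductionLog]:
    """Run the recursive reduction to a fixed point.

    Order: the first CTP in canonical order is applied; if none exists, the
    first ITP; if neither, a parallel merge.  A CTP whose transition pair
    simultaneously forms an ITP is reduced as the ITP.  After every event the
    CTP search restarts.  Unconnected vertices are removed along the way and
    in a final sweep.  Deterministic: a pure function of the input net.
    """
    work = net.copy()
    log = ReductionLog(original=net.copy())
    exprs: dict[str, MergedName] = {}
    step = 0

    def record(events: list[ReductionEvent]) -> None:
        nonlocal step
        log.events.extend(events)
        step = (events[-1].step + 1) if events else step

    while True:
        ctps = find_ctps(work, strict_weights=strict_ctp_weights)
        itps = find_itps(work)
        if ctps:
            t_i, p_c, t_j = ctps[0]
            itp_match = next(
                (q for q in itps if {q[0], q[1]} == {t_i, t_j}), None
            )
            if itp_match is not None:
                work, events = apply_itp(work, itp_match, start_step=step)
                if events[0].survivor is not None:
                    exprs[events[0].survivor] = MergedName(
                        "itp",
                        (_expr(exprs, itp_match[2]), _expr(exprs, itp_match[3])),
                    )
            else:
                work, events = apply_ctp(
                    work, (t_i, p_c, t_j), start_step=step,
                    strict_weights=strict_ctp_weights,
                )
                exprs[events[0].survivor] = MergedName(
                    "ctp", (_expr(exprs, t_i), _expr(exprs, t_j))
                )
            record(events)
            continue
        if itps:
            q = itps[0]
            work, events = apply_itp(work, q, start_step=step)
            if events[0].survivor is not None:
                exprs[events[0].survivor] = MergedName(
                    "itp", (_expr(exprs, q[2]), _expr(exprs, q[3]))
                )
            record(events)
            continue
        parallels = find_parallel(work)
        if parallels:
            work, events = merge_parallel(work, parallels[0], start_step=step)
            record(events)
            continue
        break

    tail = _cleanup_events(work, step)
    record(tail)
    log.final = work.copy()
    log.merged_names = {
        vid: e for vid, e in exprs.items()
        if vid in work.places or vid in work.transitions
    }
    return work, log


# ---------------------------------------------------------------------------
# invariant expansion


def expand_t_invariant(log: ReductionLog, y_reduced: InvariantVector) -> InvariantVector:
    """Map a TI of the reduced net back to a TI of the original net.

    A ``ctp(a + b)`` coefficient distributes to both constituents (the merged
    column is the sum of theirs); for each undone ITP the minimal number of
    firings of the removed reversible pair needed to re-balance the un-merged
    places is inserted (the token surplus of the surviving place flows to its
    partner through one direction of the pair).  The result is asserted to be
    a TI of the original net; an unbalanceable expansion raises
    :class:`ExpansionError` rather than guessing.
    """
    if log.final is None:
        raise ExpansionError("reduction log has no final net")
    if not is_t_invariant(log.final, y_reduced):
        raise ExpansionError("vector is not a TI of the reduced net")
    nets = log.nets()
    coeffs: dict[str, int] = dict(y_reduced.coeffs)
    for i in range(len(log.events) - 1, -1, -1):
        ev = log.events[i]
        before = nets[i]
        if ev.kind == "CTP":
            t_i, _, t_j = ev.candidate  # type: ignore[misc]
            c = coeffs.pop(ev.survivor, 0)
            if c:
                coeffs[t_i] = coeffs.get(t_i, 0) + c
                coeffs[t_j] = coeffs.get(t_j, 0) + c
        elif ev.kind == "ITP":
            t_i, t_j, p_i, p_j = ev.candidate  # type: ignore[misc]
            if p_j is None:
                continue  # boundary pair: place touched by nothing else
            balance = sum(
                c * (before.weight(t, p_i) - before.weight(p_i, t))
                for t, c in coeffs.items()
            )
            if balance > 0:
                coeffs[t_i] = balance  # t_i consumes p_i, produces p_j
            elif balance < 0:
                coeffs[t_j] = -balance
            check = sum(
                c * (before.weight(t, p) - before.weight(p, t))
                for p in (p_i, p_j)
                for t, c in coeffs.items()
            )
            if check != 0:
                raise ExpansionError(
                    f"could not balance places {p_i!r}/{p_j!r} while undoing "
                    f"step {ev.step}"
                )
        # PARALLEL: the removed twin keeps coefficient 0 (identical columns);
        # CLEANUP: removed vertices cannot carry reduced coefficients.
    result = InvariantVector.from_dict("transition", coeffs)
    if not is_t_invariant(log.original, result):
        raise ExpansionError(
            f"expansion of {y_reduced.render()} is not a TI of the original net"
        )
    return result
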