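"""Place/transition net data model, incidence matrix, and token-game semantics.

A place/transition net is the six-tuple (P, T, F, K, W, M0): disjoint sets of
places and transitions, a weighted flow relation F (the arcs, place<->transition
only), place capacities K (unbounded by default), and an initial marking M0.
In a metabolic reading, places are metabolite pools, transitions are reactions,
arc weights carry the stoichiometry, and tokens are discrete units of substance.

The incidence matrix C (m places x n transitions) records the net token change
on each place per single firing of each transition; it is the stoichiometry
matrix of the reaction system.  For a pair of opposite arcs between the same
place and transition (a *read arc*, modelling catalysis), the entry is the
producing weight W(t, p) -- the consuming weight is not visible in C, so nets
with read arcs are flagged by the invariant layer.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "PetriNetError",
    "MissingVertexError",
    "NotActivatedError",
    "NetStructureError",
    "Marking",
    "PetriNet",
    "IncidenceMatrix",
    "incidence_matrix",
    "token_game",
    "find_dead_markings",
    "DeadlockSearchResult",
]


class PetriNetError(Exception):
    """Base class for all petrimet errors."""


class MissingVertexError(PetriNetError, KeyError):
    """A referenced place or transition does not exist in the net."""


class NotActivatedError(PetriNetError):
    """Attempt to fire a transition that has no concession."""


class NetStructureError(PetriNetError, ValueError):
    """The net violates a structural invariant (bipartiteness, weights, ...)."""


class Marking(dict):
    """A marking M: place id -> non-negative token count.

    A plain ``dict`` subclass; absent places are read as zero via :meth:`get`
    by the semantics functions.  :meth:`key` gives a hashable canonical form
    used by the reachability search.
    """

    def copy(self) -> "Marking":
        return Marking(self)

    def key(self, place_order: Iterable[str]) -> tuple[int, ...]:
        return tuple(self.get(p, 0) for p in place_order)


@dataclass
class PetriNet:
    """A place/transition net.

    Parameters
    ----------
    places, transitions:
        Disjoint vertex id sets.
    arcs:
        Mapping ``(source, target) -> weight`` with positive integer weights;
        every arc connects a place to a transition or vice versa.
    capacities:
        Mapping place -> positive integer bound; absent places are unbounded.
    initial_marking:
        Mapping place -> token count (absent places hold zero tokens).
    logical_groups:
        Mapping display-copy id -> canonical place id.  Logical copies exist
        only in serialized layouts; after import the net holds one canonical
        place per metabolite and this mapping records the merged copies.
    """

    places: set[str] = field(default_factory=set)
    transitions: set[str] = field(default_factory=set)
    arcs: dict[tuple[str, str], int] = field(default_factory=dict)
    capacities: dict[str, int] = field(default_factory=dict)
    initial_marking: dict[str, int] = field(default_factory=dict)
    logical_groups: dict[str, str] = field(default_factory=dict)
    name: str = "net"

    def __post_init__(self) -> None:
        self.validate()

    # -- construction and validation ------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise NetStructureError on violation."""
        overlap = self.places & self.transitions
        if overlap:
            raise NetStructureError(f"place and transition ids overlap: {sorted(overlap)}")
        for (u, v), w in self.arcs.items():
            if not (isinstance(w, (int, np.integer)) and w >= 1):
                raise NetStructureError(f"arc ({u}, {v}) has non-positive weight {w!r}")
            p_to_t = u in self.places and v in self.transitions
            t_to_p = u in self.transitions and v in self.places
            if not (p_to_t or t_to_p):
                raise NetStructureError(
                    f"arc ({u}, {v}) does not connect a place with a transition"
                )
        for p, k in self.capacities.items():
            if p not in self.places:
                raise NetStructureError(f"capacity given for unknown place {p!r}")
            if not (isinstance(k, (int, np.integer)) and k >= 1):
                raise NetStructureError(f"capacity of {p!r} must be a positive integer")
        for p, m in self.initial_marking.items():
            if p not in self.places:
                raise NetStructureError(f"initial marking given for unknown place {p!r}")
            if m < 0:
                raise NetStructureError(f"negative initial marking on {p!r}")
            if m > self.capacity(p):
                raise NetStructureError(f"initial marking on {p!r} exceeds its capacity")
        for copy_id, canon in self.logical_groups.items():
            if canon not in self.places:
                raise NetStructureError(
                    f"logical copy {copy_id!r} points at unknown place {canon!r}"
                )
            if copy_id in self.places or copy_id in self.transitions:
                raise NetStructureError(
                    f"logical copy id {copy_id!r} clashes with a live vertex"
                )

    def copy(self) -> "PetriNet":
        return PetriNet(
            places=set(self.places),
            transitions=set(self.transitions),
            arcs=dict(self.arcs),
            capacities=dict(self.capacities),
            initial_marking=dict(self.initial_marking),
            logical_groups=dict(self.logical_groups),
            name=self.name,
        )

    # -- elementary accessors -------------------------------------------

    @property
    def sorted_places(self) -> tuple[str, ...]:
        return tuple(sorted(self.places))

    @property
    def sorted_transitions(self) -> tuple[str, ...]:
        return tuple(sorted(self.transitions))

    def weight(self, source: str, target: str) -> int:
        """Arc weight W(source, target); 0 if the arc is absent."""
        return self.arcs.get((source, target), 0)

    def capacity(self, place: str) -> float:
        """Capacity K(place); ``inf`` when unbounded."""
        k = self.capacities.get(place)
        return float("inf") if k is None else k

    def _require(self, v: str) -> None:
        if v not in self.places and v not in self.transitions:
            raise MissingVertexError(v)

    def pre_set(self, v: str) -> set[str]:
        """The pre-vertices of v: all y with an arc y -> v."""
        self._require(v)
        return {u for (u, w) in self.arcs if w == v}

    def post_set(self, v: str) -> set[str]:
        """The post-vertices of v: all y with an arc v -> y."""
        self._require(v)
        return {w for (u, w) in self.arcs if u == v}

    def degree(self, v: str) -> int:
        """Number of incident arcs (in + out); a read arc counts twice."""
        self._require(v)
        return sum(1 for (u, w) in self.arcs if u == v or w == v)

    def is_pure(self) -> bool:
        """True iff the net has no read arcs (no opposite-direction arc pair)."""
        return not any((v, u) in self.arcs for (u, v) in self.arcs)

    def read_arc_pairs(self) -> set[tuple[str, str]]:
        """All (place, transition) pairs joined by arcs in both directions."""
        out = set()
        for (u, v) in self.arcs:
            if (v, u) in self.arcs:
                p, t = (u, v) if u in self.places else (v, u)
                out.add((p, t))
        return out

    def input_transitions(self) -> set[str]:
        """Transitions with no pre-places; always activated."""
        return {t for t in self.transitions if not self.pre_set(t)}

    def output_transitions(self) -> set[str]:
        """Transitions with no post-places; firing removes tokens from the net."""
        return {t for t in self.transitions if not self.post_set(t)}

    def m0(self) -> Marking:
        """The initial marking with every place made explicit."""
        return Marking({p: self.initial_marking.get(p, 0) for p in self.places})

    # -- token-game semantics -------------------------------------------

    def is_activated(self, marking: Mapping[str, int], t: str) -> bool:
        """Concession test: enough tokens on pre-places, room on post-places."""
        if t not in self.transitions:
            raise MissingVertexError(t)
        for p in self.pre_set(t):
            if marking.get(p, 0) < self.weight(p, t):
                return False
        for p in self.post_set(t):
            if marking.get(p, 0) > self.capacity(p) - self.weight(t, p):
                return False
        return True

    def fire(self, marking: Mapping[str, int], t: str) -> Marking:
        """Fire t, returning the successor marking.

        Tokens are removed from pre-places and produced on post-places by arc
        weight; the read-arc case applies both. Raises
        :class:`NotActivatedError` if t has no concession (never clamps).
        """
        if not self.is_activated(marking, t):
            raise NotActivatedError(f"transition {t!r} is not activated")
        new = Marking({p: marking.get(p, 0) for p in self.places})
        for p in self.pre_set(t):
            new[p] -= self.weight(p, t)
        for p in self.post_set(t):
            new[p] += self.weight(t, p)
        return new

    def activated_transitions(self, marking: Mapping[str, int]) -> list[str]:
        return [t for t in self.sorted_transitions if self.is_activated(marking, t)]


@dataclass(frozen=True)
class IncidenceMatrix:
    """The incidence (stoichiometry) matrix C of a net.

    Rows are places, columns are transitions, both in lexicographic id order
    so matrices are reproducible bit-for-bit across runs.
    """

    places: tuple[str, ...]
    transitions: tuple[str, ...]
    matrix: np.ndarray  # shape (m, n), dtype int64

    def __getitem__(self, key: tuple[str, str]) -> int:
        p, t = key
        return int(self.matrix[self.places.index(p), self.transitions.index(t)])

    def column(self, t: str) -> dict[str, int]:
        j = self.transitions.index(t)
        return {p: int(self.matrix[i, j]) for i, p in enumerate(self.places)}

    def row(self, p: str) -> dict[str, int]:
        i = self.places.index(p)
        return {t: int(self.matrix[i, j]) for j, t in enumerate(self.transitions)}


def incidence_matrix(net: PetriNet) -> IncidenceMatrix:
    """Build C with C[i, j] = W(t_j, p_i) - W(p_i, t_j), absent arcs as 0.

    For a read arc the producing weight wins (the consuming weight is erased);
    invariant computations on such nets are flagged upstream.
    """
    places = net.sorted_places
    transitions = net.sorted_transitions
    m = np.zeros((len(places), len(transitions)), dtype=np.int64)
    for i, p in enumerate(places):
        for j, t in enumerate(transitions):
            if (t, p) in net.arcs:
                m[i, j] = net.arcs[(t, p)]
            elif (p, t) in net.arcs:
                m[i, j] = -net.arcs[(p, t)]
    return IncidenceMatrix(places, transitions, m)


def token_game(
    net: PetriNet,
    steps: int,
    seed: int,
    marking: Mapping[str, int] | None = None,
) -> list[tuple[str, Marking]]:
    """Simulate the token game: at each step a uniformly random activated
    transition fires.  Stops early at a dead marking.  Deterministic under
    a fixed seed.

    Returns the trajectory as a list of (fired transition, resulting marking).
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    rng = random.Random(seed)
    m = Marking(dict(marking) if marking is not None else net.m0())
    out: list[tuple[str, Marking]] = []
    for _ in range(steps):
        enabled = net.activated_transitions(m)
        if not enabled:
            break
        t = rng.choice(enabled)
        m = net.fire(m, t)
        out.append((t, m))
    return out


@dataclass
class DeadlockSearchResult:
    """Outcome of a bounded breadth-first reachability probe.

    ``truncated`` means the state bound was hit, so absence of dead markings
    among the explored states is *not* a deadlock-freeness claim.
    """

    dead_markings: list[Marking]
    n_explored: int
    truncated: bool

    @property
    def deadlock_free_claim(self) -> bool | None:
        """True/False when decided within the bound, None when undecided."""
        if self.dead_markings:
            return False
        return None if self.truncated else True


def find_dead_markings(
    net: PetriNet,
    m0: Mapping[str, int] | None = None,
    max_states: int = 10_000,
) -> DeadlockSearchResult:
    """Breadth-first search of the reachability set, up to ``max_states`` states,
    reporting every reached marking with no activated transition."""
    if max_states < 1:
        raise ValueError("max_states must be >= 1")
    order = net.sorted_places
    start = Marking({p: (m0 or net.m0()).get(p, 0) for p in net.places})
    seen = {start.key(order)}
    queue: deque[Marking] = deque([start])
    dead: list[Marking] = []
    truncated = False
    while queue:
        m = queue.popleft()
        enabled = net.activated_transitions(m)
        if not enabled:
            dead.append(m)
            continue
        for t in enabled:
            m2 = net.fire(m, t)
            k = m2.key(order)
            if k in seen:
                continue
            if len(seen) >= max_states:
                truncated = True
                continue
            seen.add(k)
            queue.append(m2)
    return DeadlockSearchResult(dead_markings=dead, n_explored=len(seen), truncated=truncated)
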