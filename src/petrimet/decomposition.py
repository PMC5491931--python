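"""Maximal Common Transition sets (MCT-sets).

Two transitions belong to the same MCT-set iff they participate in exactly
the same minimal TIs.  That equality of TI-membership signatures is an
equivalence relation, so the MCT-sets partition the TI-covered transitions,
and each set is either wholly inside or wholly outside every TI support.
MCT-sets are the smallest steady-state building blocks of the network and,
unlike TI subnets, need not be connected.

Transitions appearing in no TI technically share the all-zero signature;
grouping unrelated dead transitions into one module would be misleading, so
they are reported separately as an ``uncovered`` pseudo-class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import PetriNet
from .invariants import InvariantVector

__all__ = ["MCTSet", "MCTPartition", "ti_membership", "mct_sets", "mct_subnet"]


@dataclass(frozen=True)
class MCTSet:
    """An equivalence class of transitions with identical TI membership.

    ``ti_signature`` holds the indices (into the lexicographically sorted TI
    list) of the TIs every member belongs to.
    """

    members: frozenset[str]
    ti_signature: frozenset[int]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MCTPartition:
    """Proper MCT-sets plus the flagged uncovered pseudo-class."""

    sets: tuple[MCTSet, ...]
    uncovered: frozenset[str]


def _sorted_tis(tis: Iterable[InvariantVector]) -> list[InvariantVector]:
    return sorted(tis, key=lambda iv: iv.entries)


def ti_membership(
    tis: Sequence[InvariantVector], transitions: Iterable[str]
) -> tuple[np.ndarray, tuple[str, ...], tuple[InvariantVector, ...]]:
    """Binary transition x TI membership matrix.

    Rows are transitions in lexicographic order, columns are the TIs in their
    canonical (sorted) order; an entry is 1 iff the transition lies in that
    TI's support.  Returns (matrix, row ids, column TIs).
    """
    rows = tuple(sorted(transitions))
    cols = tuple(_sorted_tis(tis))
    mat = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for j, ti in enumerate(cols):
        for t in ti.support:
            if t in rows:
                mat[rows.index(t), j] = 1
    return mat, rows, cols


def mct_sets(
    net: PetriNet,
    tis: Sequence[InvariantVector],
    include_trivial: bool = True,
    reversible_pairs: set[tuple[str, str]] | None = None,
) -> MCTPartition:
    """Partition the net's transitions by identical TI-membership signature.

    With ``include_trivial=False``, trivial TIs (split reversible pairs) are
    dropped before grouping, so reversible bookkeeping does not split modules.
    """
    kept = _sorted_tis(tis)
    if not include_trivial:
        from .invariants import classify_ti

        kept = [
            ti
            for ti in kept
            if classify_ti(net, ti, reversible_pairs) != "trivial"
        ]
    signature: dict[str, frozenset[int]] = {}
    for t in net.transitions:
        signature[t] = frozenset(
            i for i, ti in enumerate(kept) if t in ti.support
        )
    groups: dict[frozenset[int], set[str]] = {}
    uncovered: set[str] = set()
    for t, sig in signature.items():
        if not sig:
            uncovered.add(t)
        else:
            groups.setdefault(sig, set()).add(t)
    sets = tuple(
        sorted(
            (MCTSet(frozenset(members), sig) for sig, members in groups.items()),
            key=lambda s: sorted(s.members),
        )
    )
    return MCTPartition(sets=sets, uncovered=frozenset(uncovered))


def mct_subnet(net: PetriNet, s: MCTSet) -> PetriNet:
    """Induced subnet of an MCT-set: members, neighboring places, and all
    arcs in between.  Connectivity is *not* asserted."""
    vertices = set(s.members)
    for t in s.members:
        vertices |= net.pre_set(t) | net.post_set(t)
    return PetriNet(
        places=vertices & net.places,
        transitions=vertices & net.transitions,
        arcs={
            (u, v): w
            for (u, v), w in net.arcs.items()
            if u in vertices and v in vertices
        },
        capacities={p: k for p, k in net.capacities.items() if p in vertices},
        initial_marking={p: m for p, m in net.initial_marking.items() if p in vertices},
        name=f"{net.name}|mct({'+'.join(sorted(s.members))})",
    )
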