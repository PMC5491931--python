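"""Minimal semi-positive place- and transition-invariants, coverage, classes.

A transition invariant (TI) is a non-negative integer firing-count vector y
with C.y = 0: firing every transition in y its given number of times returns
the net to the marking it started from, so the support of a TI is a candidate
steady-state pathway (the metabolic reading of an elementary mode).  A place
invariant (PI) is a non-negative integer weighting x with C^T.x = 0, a token
conservation law.  We enumerate the *minimal* invariants: gcd of the non-zero
entries is one, and no other invariant's support is strictly contained in
theirs.  Every minimal invariant of a net is found; the computation is exact
integer arithmetic throughout.

The enumeration is a Fourier-Motzkin style pairwise-combination pass over the
integer kernel (rows start as unit vectors annotated with their incidence
column; each constraint row of C is eliminated in turn by combining positive
and negative rows), with support-minimality pruning after every elimination
step.  An intermediate-row cap guards against the combinatorial explosion
that makes full-size metabolic models uncomputable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import gcd
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .core import (
    IncidenceMatrix,
    NetStructureError,
    PetriNet,
    PetriNetError,
    incidence_matrix,
)

__all__ = [
    "InvariantVector",
    "DimensionError",
    "KindMismatchError",
    "CapExceededError",
    "TooLargeError",
    "SubnetDisconnectedError",
    "CoverageReport",
    "TI_CLASSES",
    "is_t_invariant",
    "is_p_invariant",
    "minimal_t_invariants",
    "minimal_p_invariants",
    "brute_force_minimal_invariants",
    "detect_reversible_pairs",
    "classify_ti",
    "classify_all",
    "coverage",
    "invariant_subnet",
]

TI_CLASSES = ("trivial", "INOUT", "IN", "OUT", "CYC")


class DimensionError(PetriNetError, ValueError):
    """Invariant vector is not indexed by the net's vertex set."""


class KindMismatchError(PetriNetError, ValueError):
    """Mixed place/transition invariants where one kind was required."""


class CapExceededError(PetriNetError, RuntimeError):
    """The intermediate-vector cap was hit during invariant enumeration."""


class TooLargeError(PetriNetError, ValueError):
    """Net too large for the exhaustive brute-force oracle."""


class SubnetDisconnectedError(NetStructureError):
    """A TI-induced subnet failed its connectedness assertion."""


@dataclass(frozen=True)
class InvariantVector:
    """A semi-positive integer invariant (Parikh vector).

    ``kind`` is ``"transition"`` or ``"place"``; ``entries`` stores the
    non-zero coefficients as a sorted tuple of (vertex id, coefficient).
    """

    kind: str
    entries: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, kind: str, coeffs: Mapping[str, int]) -> "InvariantVector":
        items = tuple(sorted((v, int(c)) for v, c in coeffs.items() if c != 0))
        if any(c < 0 for _, c in items):
            raise ValueError("invariant coefficients must be non-negative")
        return cls(kind, items)

    @property
    def coeffs(self) -> dict[str, int]:
        return dict(self.entries)

    @property
    def support(self) -> frozenset[str]:
        return frozenset(v for v, _ in self.entries)

    def __getitem__(self, v: str) -> int:
        return self.coeffs.get(v, 0)

    def __bool__(self) -> bool:
        return bool(self.entries)

    def render(self) -> str:
        """Human-readable form, e.g. ``t1 + t2 + 4*t3``."""
        return " + ".join(
            (f"{c}*{v}" if c != 1 else v) for v, c in self.entries
        )


# ---------------------------------------------------------------------------
# membership tests


def _check_indexed(vertices: set[str], y: InvariantVector, kind: str) -> None:
    if y.kind != kind:
        raise DimensionError(f"expected a {kind} invariant, got kind={y.kind!r}")
    extra = y.support - vertices
    if extra:
        raise DimensionError(f"vector indexed by unknown vertices: {sorted(extra)}")


def is_t_invariant(net: PetriNet, y: InvariantVector) -> bool:
    """Exact integer check of C.y = 0 (the zero vector is rejected)."""
    _check_indexed(net.transitions, y, "transition")
    if not y:
        return False
    C = incidence_matrix(net)
    for p in C.places:
        row = C.row(p)
        if sum(row[t] * y[t] for t in C.transitions) != 0:
            return False
    return True


def is_p_invariant(net: PetriNet, x: InvariantVector) -> bool:
    """Exact integer check of C^T.x = 0 (the zero vector is rejected)."""
    _check_indexed(net.places, x, "place")
    if not x:
        return False
    C = incidence_matrix(net)
    for t in C.transitions:
        col = C.column(t)
        if sum(col[p] * x[p] for p in C.places) != 0:
            return False
    return True


# ---------------------------------------------------------------------------
# enumeration


def _normalize_row(y: list[int], c: list[int]) -> None:
    g = 0
    for v in itertools.chain(y, c):
        g = gcd(g, v)
    if g > 1:
        for i in range(len(y)):
            y[i] //= g
        for i in range(len(c)):
            c[i] //= g


def _support(y: Sequence[int]) -> frozenset[int]:
    return frozenset(i for i, v in enumerate(y) if v != 0)


def _prune_minimal(rows: list[tuple[list[int], list[int]]]) -> list[tuple[list[int], list[int]]]:
    """Drop rows whose variable-part support strictly contains another row's,
    and exact duplicates.  Keeping only support-minimal rows at every step is
    the classical completeness-preserving pruning for minimal semiflows."""
    seen: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    uniq: list[tuple[list[int], list[int]]] = []
    for y, c in rows:
        k = (tuple(y), tuple(c))
        if k not in seen:
            seen.add(k)
            uniq.append((y, c))
    supports = [_support(y) for y, _ in uniq]
    keep = []
    for i, (y, c) in enumerate(uniq):
        si = supports[i]
        dominated = any(
            j != i and supports[j] < si for j in range(len(uniq))
        )
        if not dominated:
            keep.append((y, c))
    return keep


def _minimal_semiflows(
    columns: dict[str, list[int]],
    n_constraints: int,
    max_intermediate: int,
) -> list[dict[str, int]]:
    """All minimal semi-positive integer vectors y with sum_v y_v * col_v = 0.

    ``columns[v]`` is the length-``n_constraints`` constraint column of
    variable v.  Pure-Python big integers, so no overflow.
    """
    ids = sorted(columns)
    rows: list[tuple[list[int], list[int]]] = []
    for i, v in enumerate(ids):
        y = [0] * len(ids)
        y[i] = 1
        rows.append((y, list(columns[v])))

    for k in range(n_constraints):
        zero, pos, neg = [], [], []
        for y, c in rows:
            (zero if c[k] == 0 else pos if c[k] > 0 else neg).append((y, c))
        new_rows = list(zero)
        for (yp, cp) in pos:
            for (yn, cn) in neg:
                a, b = cp[k], -cn[k]
                g = gcd(a, b)
                fa, fb = b // g, a // g
                y = [fa * u + fb * v for u, v in zip(yp, yn)]
                c = [fa * u + fb * v for u, v in zip(cp, cn)]
                _normalize_row(y, c)
                new_rows.append((y, c))
        rows = _prune_minimal(new_rows)
        if len(rows) > max_intermediate:
            raise CapExceededError(
                f"invariant enumeration exceeded the cap of {max_intermediate} "
                f"intermediate vectors after eliminating {k + 1}/{n_constraints} "
                "constraints; raise max_intermediate or reduce the net first"
            )

    out = []
    for y, c in rows:
        assert all(v == 0 for v in c)
        g = 0
        for v in y:
            g = gcd(g, v)
        if g == 0:
            continue
        out.append({ids[i]: v // g for i, v in enumerate(y) if v != 0})
    return out


def _warn_read_arcs(net: PetriNet) -> None:
    if not net.is_pure():
        warnings.warn(
            f"net {net.name!r} contains read arcs; the incidence matrix erases "
            "their consuming weights, so invariants are computed on the printed "
            "(producer-wins) matrix",
            stacklevel=3,
        )


def minimal_t_invariants(
    net: PetriNet, max_intermediate: int = 200_000
) -> list[InvariantVector]:
    """The complete, duplicate-free set of minimal semi-positive TIs.

    Output is sorted lexicographically by entry tuple for reproducibility.
    Raises :class:`CapExceededError` if the intermediate-vector cap is hit.
    """
    _warn_read_arcs(net)
    C = incidence_matrix(net)
    cols = {t: [int(v) for v in C.matrix[:, j]] for j, t in enumerate(C.transitions)}
    flows = _minimal_semiflows(cols, len(C.places), max_intermediate)
    return sorted(
        (InvariantVector.from_dict("transition", f) for f in flows),
        key=lambda iv: iv.entries,
    )


def minimal_p_invariants(
    net: PetriNet, max_intermediate: int = 200_000
) -> list[InvariantVector]:
    """The complete, duplicate-free set of minimal semi-positive PIs."""
    _warn_read_arcs(net)
    C = incidence_matrix(net)
    cols = {p: [int(v) for v in C.matrix[i, :]] for i, p in enumerate(C.places)}
    flows = _minimal_semiflows(cols, len(C.transitions), max_intermediate)
    return sorted(
        (InvariantVector.from_dict("place", f) for f in flows),
        key=lambda iv: iv.entries,
    )


def brute_force_minimal_invariants(
    net: PetriNet,
    coeff_bound: int,
    kind: str = "transition",
) -> list[InvariantVector]:
    """Independent exhaustive oracle for small nets (testing only).

    Enumerates every non-zero vector with entries in [0, coeff_bound], keeps
    kernel members, gcd-reduces, and filters to support-minimal vectors.
    A minimal invariant with a coefficient above the bound is missed -- a
    documented limitation of the oracle, not of the main enumeration.
    """
    if coeff_bound < 1:
        raise ValueError("coeff_bound must be >= 1")
    vertices = net.sorted_transitions if kind == "transition" else net.sorted_places
    if len(vertices) > 8:
        raise TooLargeError(
            f"brute-force oracle guard: {len(vertices)} {kind}s > 8"
        )
    check = is_t_invariant if kind == "transition" else is_p_invariant
    found: set[tuple[tuple[str, int], ...]] = set()
    for combo in itertools.product(range(coeff_bound + 1), repeat=len(vertices)):
        if not any(combo):
            continue
        iv = InvariantVector.from_dict(kind, dict(zip(vertices, combo)))
        if not check(net, iv):
            continue
        g = 0
        for c in combo:
            g = gcd(g, c)
        if g > 1:
            iv = InvariantVector.from_dict(
                kind, {v: c // g for v, c in iv.entries}
            )
        found.add(iv.entries)
    ivs = [InvariantVector(kind, e) for e in sorted(found)]
    minimal = [
        iv
        for iv in ivs
        if not any(o.support < iv.support for o in ivs if o is not iv)
    ]
    return minimal


# ---------------------------------------------------------------------------
# classification and coverage


def detect_reversible_pairs(net: PetriNet) -> set[tuple[str, str]]:
    """Forward/backward transition pairs of split reversible reactions.

    A pair is detected structurally (t and t' with mirrored pre/post sets and
    matching weights) or by the ``_f``/``_b`` name-suffix convention used in
    reaction tables.  Returned as sorted 2-tuples.
    """
    pairs: set[tuple[str, str]] = set()
    ts = net.sorted_transitions
    pre = {t: net.pre_set(t) for t in ts}
    post = {t: net.post_set(t) for t in ts}
    for i, t in enumerate(ts):
        for u in ts[i + 1 :]:
            if pre[t] == post[u] and post[t] == pre[u] and pre[t] | post[t]:
                if all(net.weight(p, t) == net.weight(u, p) for p in pre[t]) and all(
                    net.weight(t, p) == net.weight(p, u) for p in post[t]
                ):
                    pairs.add((t, u))
    for t in ts:
        if t.endswith("_f"):
            twin = t[:-2] + "_b"
            if twin in net.transitions:
                pairs.add(tuple(sorted((t, twin))))  # type: ignore[arg-type]
    return pairs


def classify_ti(
    net: PetriNet,
    y: InvariantVector,
    reversible_pairs: set[tuple[str, str]] | None = None,
) -> str:
    """Classify a TI as trivial / INOUT / IN / OUT / CYC.

    trivial: the support is exactly a declared (or detected) reversible
    forward/backward pair, each firing once.  Otherwise the class follows
    from the presence of input/output transitions in the support; a TI with
    neither is an internal cycle (CYC).
    """
    if reversible_pairs is None:
        reversible_pairs = detect_reversible_pairs(net)
    supp = y.support
    for a, b in reversible_pairs:
        if supp == {a, b} and y[a] == 1 and y[b] == 1:
            return "trivial"
    has_in = bool(supp & net.input_transitions())
    has_out = bool(supp & net.output_transitions())
    if has_in and has_out:
        return "INOUT"
    if has_in:
        return "IN"
    if has_out:
        return "OUT"
    return "CYC"


def classify_all(
    net: PetriNet,
    tis: Iterable[InvariantVector],
    reversible_pairs: set[tuple[str, str]] | None = None,
) -> dict[str, int]:
    """Class-count table over a TI set, shaped like the standard report:
    All / trivial / INOUT / IN / OUT / CYC."""
    if reversible_pairs is None:
        reversible_pairs = detect_reversible_pairs(net)
    counts = {c: 0 for c in TI_CLASSES}
    n = 0
    for y in tis:
        counts[classify_ti(net, y, reversible_pairs)] += 1
        n += 1
    return {"All": n, **counts}


@dataclass(frozen=True)
class CoverageReport:
    """Whether every transition (or place) lies in some invariant's support."""

    kind: str
    covered: bool
    uncovered: frozenset[str]


def coverage(
    net: PetriNet,
    invs: Sequence[InvariantVector],
    kind: str | None = None,
) -> CoverageReport:
    """CTI/CPI check: covered iff every transition (resp. place) is in the
    support of at least one invariant.  ``kind`` is inferred from ``invs``
    and must be given explicitly for an empty set."""
    kinds = {iv.kind for iv in invs}
    if len(kinds) > 1:
        raise KindMismatchError(f"mixed invariant kinds: {sorted(kinds)}")
    if kinds:
        inferred = kinds.pop()
        if kind is not None and kind != inferred:
            raise KindMismatchError(f"kind={kind!r} but invariants are {inferred!r}")
        kind = inferred
    elif kind is None:
        raise KindMismatchError("empty invariant set: pass kind explicitly")
    vertices = net.transitions if kind == "transition" else net.places
    hit: set[str] = set()
    for iv in invs:
        hit |= iv.support
    uncovered = frozenset(vertices - hit)
    return CoverageReport(kind=kind, covered=not uncovered, uncovered=uncovered)


def invariant_subnet(net: PetriNet, y: InvariantVector) -> PetriNet:
    """The subnet induced by an invariant: its support, the support's pre- and
    post-vertices, and all arcs in between.

    For a TI the result must be connected (asserted; a disconnected result
    raises :class:`SubnetDisconnectedError`).  MCT subnets, by contrast, may
    legitimately be disconnected and are built elsewhere.
    """
    supp = set(y.support)
    neighbors: set[str] = set()
    for v in supp:
        neighbors |= net.pre_set(v) | net.post_set(v)
    vertices = supp | neighbors
    sub = PetriNet(
        places=vertices & net.places,
        transitions=vertices & net.transitions,
        arcs={
            (u, v): w for (u, v), w in net.arcs.items() if u in vertices and v in vertices
        },
        capacities={p: k for p, k in net.capacities.items() if p in vertices},
        initial_marking={
            p: m for p, m in net.initial_marking.items() if p in vertices
        },
        name=f"{net.name}|{y.render()}",
    )
    if y.kind == "transition" and vertices:
        g = nx.Graph()
        g.add_nodes_from(vertices)
        g.add_edges_from(sub.arcs)
        if not nx.is_connected(g):
            raise SubnetDisconnectedError(
                f"TI subnet for {y.render()} is not connected"
            )
    return sub
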