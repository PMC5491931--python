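"""Built-in worked-example nets and a generator of metabolic-like CTI nets.

The two small fixture nets are classroom-sized examples exercising every
analysis: a three-transition producer/consumer net with a single weighted TI
and no PIs, and a five-transition branching net containing a reversible pair
that forms an invariant transition pair (ITP).

The random generator emulates the gross architecture of a curated metabolic
model: a union of linear input -> chain -> output pathways with unit
stoichiometry, optional place sharing across pathways (branch points),
optional reversible twins (which create trivial TIs), and optional heavier
balanced stoichiometry on single reactions.  Each pathway's indicator vector
is a transition invariant by construction and reversible twins are covered
by their trivial TIs, so every generated net is covered by TIs (CTI).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core import PetriNet

__all__ = ["SynthConfig", "fig1_net", "fig5_net", "random_cti_net", "degree_distribution"]


def fig1_net() -> PetriNet:
    """Two places, three transitions: input t1 produces 3 p1 + 2 p2; t2 turns
    2 p2 into one p1; output t3 drains p1.  Exactly one minimal TI,
    (t1 + t2 + 4 t3), no PIs, and no reducible patterns under the weight-1
    rules."""
    return PetriNet(
        places={"p1", "p2"},
        transitions={"t1", "t2", "t3"},
        arcs={
            ("t1", "p1"): 3,
            ("t1", "p2"): 2,
            ("p2", "t2"): 2,
            ("t2", "p1"): 1,
            ("p1", "t3"): 1,
        },
        name="fig1",
    )


def fig5_net() -> PetriNet:
    """Input t1 feeds places p1 and p2; t2/t3 form a reversible pair between
    them (an ITP); outputs t4 and t5 drain p1 and p2.  CTI; reducing the ITP
    merges p1 and p2 into one place fed by t1 with weight 2."""
    return PetriNet(
        places={"p1", "p2"},
        transitions={"t1", "t2", "t3", "t4", "t5"},
        arcs={
            ("t1", "p1"): 1,
            ("t1", "p2"): 1,
            ("p1", "t2"): 1,
            ("t2", "p2"): 1,
            ("p2", "t3"): 1,
            ("t3", "p1"): 1,
            ("p1", "t4"): 1,
            ("p2", "t5"): 1,
        },
        name="fig5",
    )


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the pathway-structured generator.

    n_pathways:   number of linear input->chain->output pathways.
    chain_length: (min, max) number of internal chain reactions per pathway.
    p_share:      probability that an internal place of a later pathway is
                  identified with a place of an earlier pathway (branching).
    p_reversible: probability that a chain reaction gets a backward twin,
                  named with the _f/_b suffix convention.
    p_heavy:      probability that a chain reaction carries weight 2 on both
                  of its arcs (balanced, so the net stays CTI) to exercise
                  the weight-1 exclusions of the reduction rules.
    seed:         generator seed; the same seed yields the identical net.
    """

    n_pathways: int = 3
    chain_length: tuple[int, int] = (3, 6)
    p_share: float = 0.2
    p_reversible: float = 0.3
    p_heavy: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.chain_length
        if not (1 <= lo <= hi):
            raise ValueError("chain_length must satisfy 1 <= min <= max")
        for name in ("p_share", "p_reversible", "p_heavy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")


def random_cti_net(cfg: SynthConfig) -> PetriNet:
    """Generate a pathway-structured net that is CTI by construction."""
    rng = random.Random(cfg.seed)
    places: set[str] = set()
    transitions: set[str] = set()
    arcs: dict[tuple[str, str], int] = {}

    def add_arc(u: str, v: str, w: int) -> None:
        arcs[(u, v)] = w

    shareable: list[str] = []  # internal places of earlier pathways
    for k in range(cfg.n_pathways):
        n_reactions = rng.randint(*cfg.chain_length)
        # IN -> m0 -> R1 -> m1 -> ... -> Rn -> mn -> OUT: n reactions, n+1 places
        chain_places: list[str] = []
        for i in range(n_reactions + 1):
            pid = f"m{k}_{i}"
            if k > 0 and 0 < i < n_reactions and shareable and rng.random() < cfg.p_share:
                shared = rng.choice(shareable)
                # a place may appear once per chain, else a reaction would
                # need it as pre- and post-place at once (a read arc)
                pid = shared if shared not in chain_places else pid
            if pid.startswith(f"m{k}_"):
                places.add(pid)
            chain_places.append(pid)
        t_in = f"IN_{k}"
        t_out = f"OUT_{k}"
        transitions |= {t_in, t_out}
        add_arc(t_in, chain_places[0], 1)
        add_arc(chain_places[-1], t_out, 1)
        for i in range(n_reactions):
            heavy = 2 if rng.random() < cfg.p_heavy else 1
            rev = rng.random() < cfg.p_reversible and heavy == 1
            rid = f"R{k}_{i}" + ("_f" if rev else "")
            transitions.add(rid)
            add_arc(chain_places[i], rid, heavy)
            add_arc(rid, chain_places[i + 1], heavy)
            if rev:
                bid = f"R{k}_{i}_b"
                transitions.add(bid)
                add_arc(chain_places[i + 1], bid, 1)
                add_arc(bid, chain_places[i], 1)
        shareable.extend(p for p in chain_places[1:-1] if p.startswith(f"m{k}_"))

    return PetriNet(
        places=places,
        transitions=transitions,
        arcs=arcs,
        name=f"synth(seed={cfg.seed})",
    )


def degree_distribution(net: PetriNet) -> dict[int, int]:
    """Histogram of total (in + out) arc degree over all vertices; used to
    check that a reduced net still looks like a real-world network."""
    hist: dict[int, int] = {}
    for v in sorted(net.places | net.transitions):
        d = net.degree(v)
        hist[d] = hist.get(d, 0) + 1
    return hist
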