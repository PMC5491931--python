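from pathlib import Path

import pytest

from petrimet import PetriNet, fig1_net, fig5_net

FIXTURES_DIR = Path(__file__).resolve().parent.parent / "fixtures"


@pytest.fixture
def fig1() -> PetriNet:
    return fig1_net()


@pytest.fixture
def fig5() -> PetriNet:
    return fig5_net()


@pytest.fixture
def fixtures_dir() -> Path:
    return FIXTURES_DIR


def chain_net(n: int = 4, name: str = "chain") -> PetriNet:
    """IN -> m0 -> R0 -> m1 -> ... -> R(n-1) -> mn -> OUT, unit weights."""
    places = {f"m{i}" for i in range(n + 1)}
    transitions = {"IN", "OUT"} | {f"R{i}" for i in range(n)}
    arcs = {("IN", "m0"): 1, (f"m{n}", "OUT"): 1}
    for i in range(n):
        arcs[(f"m{i}", f"R{i}")] = 1
        arcs[(f"R{i}", f"m{i + 1}")] = 1
    return PetriNet(places=places, transitions=transitions, arcs=arcs, name=name)


@pytest.fixture
def chain4() -> PetriNet:
    return chain_net(4)
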