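"""One-call analysis pipeline bundling invariants, classes, coverage, MCT-sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core import PetriNet
from .decomposition import MCTPartition, mct_sets
from .invariants import (
    CoverageReport,
    InvariantVector,
    classify_all,
    classify_ti,
    coverage,
    detect_reversible_pairs,
    minimal_p_invariants,
    minimal_t_invariants,
)

__all__ = ["AnalysisResults", "analyze"]


@dataclass
class AnalysisResults:
    """Everything the verification workflow computes for one net."""

    net: PetriNet
    tis: Sequence[InvariantVector] | None = None
    ti_classes: list[str] | None = None
    class_counts: dict[str, int] = field(default_factory=dict)
    ti_coverage: CoverageReport | None = None
    pis: Sequence[InvariantVector] | None = None
    pi_coverage: CoverageReport | None = None
    mct: MCTPartition | None = None
    reduction_log: object | None = None

    def summary(self) -> str:
        """One-line human verdict, e.g. ``CTI: yes; PIs: 0; TIs: 1 (INOUT: 1)``."""
        parts = []
        if self.ti_coverage is not None:
            if self.net.transitions:
                parts.append(f"CTI: {'yes' if self.ti_coverage.covered else 'no'}")
            else:
                parts.append("CTI: yes (vacuous: no transitions)")
        if self.pis is not None:
            parts.append(f"PIs: {len(self.pis)}")
        if self.tis is not None:
            inner = ", ".join(
                f"{k}: {v}"
                for k, v in self.class_counts.items()
                if k != "All" and v
            )
            parts.append(f"TIs: {len(self.tis)}" + (f" ({inner})" if inner else ""))
        if self.mct is not None:
            parts.append(f"MCT-sets: {len(self.mct.sets)}")
        return "; ".join(parts)


def analyze(
    net: PetriNet,
    with_pis: bool = True,
    with_mct: bool = True,
    include_trivial_in_mct: bool = True,
    max_intermediate: int = 200_000,
) -> AnalysisResults:
    """Compute minimal TIs (and optionally PIs), classify them, check
    CTI/CPI coverage, and group transitions into MCT-sets."""
    pairs = detect_reversible_pairs(net)
    tis = minimal_t_invariants(net, max_intermediate=max_intermediate)
    res = AnalysisResults(net=net, tis=tis)
    res.ti_classes = [classify_ti(net, y, pairs) for y in tis]
    res.class_counts = classify_all(net, tis, pairs)
    res.ti_coverage = coverage(net, tis, kind="transition")
    if with_pis:
        res.pis = minimal_p_invariants(net, max_intermediate=max_intermediate)
        res.pi_coverage = coverage(net, res.pis, kind="place")
    if with_mct:
        res.mct = mct_sets(
            net, tis, include_trivial=include_trivial_in_mct, reversible_pairs=pairs
        )
    return res
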