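# petrimet

Qualitative analysis of metabolic models expressed as Place/Transition Petri
nets: token-game simulation, minimal semi-positive place/transition
invariants, coverage (CTI/CPI) verification, TI classification, MCT-set
decomposition, and CTI-preserving network reduction with traceable logs and
expansion of reduced invariants back to the original net.

## Who this is for

Modellers who curate discrete, semi-quantitative metabolic networks — places
are metabolite pools, transitions are reactions, arc weights carry the
stoichiometry — and who need to verify a hand-built model for consistency
before quantitative work.  The standard consistency criterion is that the
net be *covered by transition invariants* (CTI): every reaction takes part
in at least one steady-state behaviour.  Because enumerating all minimal
invariants is infeasible for large models, the toolkit also implements
structural reductions that shrink the net while preserving the CTI property
and keeping every reduced invariant mappable back to the original network.

## The mathematics in brief

For a net with incidence (stoichiometry) matrix `C` (rows = places,
columns = transitions, `C[p,t]` = net token change on `p` when `t` fires):

* a **transition invariant (TI)** is an integer vector `y ≥ 0`, `y ≠ 0`,
  with `C·y = 0` — a firing-count (Parikh) vector that reproduces the
  marking it started from, i.e. a steady-state pathway (the Petri-net
  counterpart of an elementary mode);
* a **place invariant (PI)** is `x ≥ 0`, `x ≠ 0`, with `Cᵀ·x = 0` — a
  weighted token conservation law;
* a **minimal** invariant has gcd 1 and a support that strictly contains no
  other invariant's support.  The package enumerates the complete minimal
  set by Fourier–Motzkin-style pairwise combination over the integer kernel
  with support-minimality pruning, in exact integer arithmetic;
* **TI classes**: `trivial` (a split reversible reaction firing forward and
  back once), `INOUT`/`IN`/`OUT` (by boundary transitions in the support),
  `CYC` (internal cycle);
* **MCT-sets** group transitions that occur in exactly the same minimal TIs
  — the smallest steady-state building blocks;
* **reduction**: common transition pairs (`ctp(t_i + t_j)` merges a chain
  through a 1-in/1-out place), invariant transition pairs (`itp(p_i + p_j)`
  merges the two places of a reversible pair), and parallel-transition
  merges, applied recursively with a deterministic order and an event log
  that replays exactly and supports invariant expansion.

## Worked example

```python
>>> from petrimet import fig5_net, minimal_t_invariants, reduce_net, expand_t_invariant
>>> net = fig5_net()          # input t1 -> {p1, p2}; reversible t2/t3; outputs t4, t5
>>> [y.render() for y in minimal_t_invariants(net)]
['t1 + t2 + 2*t5', 't1 + t3 + 2*t4', 't1 + t4 + t5', 't2 + t3']
>>> reduced, log = reduce_net(net)
>>> sorted(reduced.places), sorted(reduced.transitions)
(['itp(p1 + p2)'], ['t1', 't4', 't5'])
>>> reduced.arcs[('t1', 'itp(p1 + p2)')]
2
>>> [expand_t_invariant(log, y).render() for y in minimal_t_invariants(reduced)]
['t1 + t3 + 2*t4', 't1 + t2 + 2*t5']
```

The reversible pair t2/t3 is an invariant transition pair, so one reduction
event merges p1 and p2 into a single place whose inbound arc weight is the
sum of the two original arcs.  The reduced net keeps exactly two minimal TIs
(`t1 + t4 + t5` is no longer support-minimal there), and expanding them
re-inserts the single firing of the removed reversible transition needed to
rebalance the un-merged places — both expansions satisfy `C·y = 0` on the
original net.

The `examples/` directory holds one short narrative script per capability
(simulation, invariant analysis, reduction + expansion, MCT decomposition,
synthetic screening); each prints the numbers it computes and says what they
mean.  A thin CLI wraps the same calls:

```sh
petrimet analyze fixtures/fig1.pnml        # -> CTI: yes; PIs: 0; TIs: 1 (INOUT: 1); MCT-sets: 1
petrimet reduce fixtures/fig5.pnml --out out/
```

## File formats

Nets are read and written as PNML (ISO 15909-2 P/T subset) or as a
reaction-table TSV (one reaction per row; reversible records expand to
`_f`/`_b` transition pairs).  See `docs/formats.md` for the grammar;
`fixtures/` ships both example nets in both formats.

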