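# Methods

## Model

A Place/Transition net is the six-tuple (P, T, F, K, W, M0).  Places model
metabolite pools, transitions model reactions, and the weighted flow
relation carries the stoichiometry.  The firing rule is the classical one:
a transition has concession when every pre-place holds at least the arc
weight in tokens and every post-place has capacity room; firing moves
tokens accordingly.  Input transitions (no pre-places) are always activated
and model uptake from the environment; output transitions model export.
Capacities default to unbounded, which is the usual choice for metabolic
models; they are honoured by the token game but ignored by invariant
computations, which are marking-independent.

Read arcs (a place that is both pre- and post-place of one transition,
modelling catalysis) are stored as two opposite arcs.  The incidence matrix
uses the producer-wins convention for such pairs: `C[p,t] = W(t,p)` when
both arcs exist, which erases the consuming weight.  This is deliberate —
it is the printed textbook definition — but it means invariants computed on
impure nets describe the producer-wins matrix, not the token game; the
invariant layer therefore emits a warning for any net with read arcs.

Logical place copies (layout duplicates of a hub metabolite such as ATP)
exist only in serialized files; the PNML reader folds every copy into its
canonical place and records the merge in `logical_groups`, so analysis
never sees duplicates.

## Minimal invariant enumeration

We enumerate minimal semi-positive integer solutions of `C·y = 0` (TIs) and
`Cᵀ·x = 0` (PIs).  The algorithm is the classical Fourier–Motzkin /
pairwise-combination scheme over the integer kernel: start from unit
vectors annotated with their constraint columns, eliminate one constraint
row at a time by combining each positive row with each negative row (scaled
by the gcd of the pivots), gcd-normalize every row, and after each
elimination drop exact duplicates and every row whose variable-part support
strictly contains another row's support.  Support-minimality pruning at
every step is what keeps the intermediate sets near the final answer and is
completeness-preserving for minimal semiflows.  All arithmetic is exact
(Python integers); constraint elimination order is lexicographic by vertex
id, and outputs are sorted, so results are bit-identical across runs.

Enumeration is worst-case exponential — full-size metabolic models are
routinely uncomputable — so a configurable cap on the intermediate row
count (default 200,000) aborts with a diagnostic rather than exhausting
memory.  The CLI maps this to its own exit code (3), distinct from parse
errors (2).

An independent exhaustive oracle (`brute_force_minimal_invariants`) checks
every vector with entries in `[0, bound]` on nets of at most 8 transitions.
It exists for testing only; a minimal invariant with a coefficient beyond
the bound is invisible to it, which the tests account for when choosing
bounds.

### Classification

A TI is `trivial` when its support is exactly a declared reversible
forward/backward pair, each firing once.  Reversible pairs are detected
structurally (mirrored pre/post sets with matching weights) and by the
`_f`/`_b` suffix convention; an explicit declaration overrides detection.
Note that a two-transition cycle is structurally indistinguishable from a
split reversible reaction and classifies as trivial unless the caller
passes an overriding (e.g. empty) pair set.  Otherwise the class follows
from boundary transitions in the support: INOUT, IN, OUT, or CYC.

## MCT-sets

Transitions are grouped by their membership signature across the minimal
TIs.  Signature equality is an equivalence relation, so the groups
partition the covered transitions; each group is wholly inside or wholly
outside every TI support, and every TI support is a union of whole groups
(all three laws are property-tested).  Transitions occurring in no TI share
the all-zero signature, but grouping unrelated dead reactions into one
"module" would be misleading, so they are excluded from proper MCT-sets and
reported as a flagged `uncovered` pseudo-class.  Whether trivial TIs
participate in the grouping is a flag (`include_trivial`, default on):
including them splits reversible bookkeeping into its own sets, excluding
them yields coarser functional modules.

## Reduction

Three structural patterns are merged, each preserving coverage by TIs:

* **CTP** — a connecting place with exactly one pre-transition and one
  post-transition.  The post-transition and the place are deleted; the
  pre-transition absorbs the remainder and is renamed `ctp(t_i + t_j)`.
  Both arcs through the connecting place must have weight 1.  The weight
  condition for CTPs is not forced by the pattern itself, but relaxing it
  breaks stoichiometric balance of the merged column, so weight-1 is the
  default with a documented `strict_weights=False` escape hatch.
* **ITP** — a reversible pair reciprocally connecting two places, all four
  arcs of weight 1 (here the weight condition is essential).  Both
  transitions and one place are deleted; the surviving place absorbs arcs
  and marking (tokens add — the only conservation-respecting choice) and is
  renamed `itp(p_i + p_j)`.  For suffix-named pairs the forward reaction's
  substrate place survives, matching the naming convention of curated
  models.  A place wired only to one dedicated input and one dedicated
  output transition is the boundary special case of an ITP and is deleted
  outright.
* **PARALLEL** — two transitions with identical single pre- and post-places
  and unit weights collapse to one; the canonical-first survivor keeps its
  name and the pair is recorded in the log.

Merging is exact incidence arithmetic: the merged transition's column is
the *sum* of its constituents' columns (resp. the merged place's row the
sum of the rows).  Opposite-direction arcs between the merged vertex and a
neighbor are netted into a single arc of the difference weight.  Netting is
what makes the bookkeeping exact, and two classical behaviours fall out of
it as special cases: a CTP whose pair is mutually reversible on all other
places cancels completely and the merged transition disappears, and after
an ITP any duplicate reversible pair over the same two places degenerates
to arc-less transitions.  Vertices left without arcs are removed and logged
as CLEANUP events.

The loop applies the first CTP in canonical (lexicographic) order,
otherwise the first ITP, otherwise a parallel merge, and restarts the CTP
search after every event.  A candidate that is simultaneously a CTP and an
ITP (a place attached to the net only through a reversible pair) is reduced
as the ITP.  Every event strictly decreases |P| + |T|, so termination is
immediate.  Candidate order makes `reduce_net` a pure function of the input
net; we fix one canonical order and make no confluence claim — tests
compare invariant sets, not event counts, across nets.  A maximally
reducible net (a single linear chain) legitimately reduces to the empty
net: the end-to-end merge leaves one input and one output transition on one
place, the boundary ITP case, after which nothing remains.

The ordered event log stores each candidate in the vertex names current at
its step, so replaying the log on the original net reproduces the reduced
net exactly (asserted in tests, arcs and markings included), and the
surviving merged names carry their full expression trees over original ids.

### Expansion of reduced invariants

A TI of the reduced net maps back by reversing the log.  Undoing a CTP
distributes the merged coefficient to both constituents (the merged column
was their sum).  Undoing an ITP re-inserts firings of the removed
reversible pair: the surviving place's token balance under the partial
expansion, computed on the net as it stood before that event, is shifted to
its partner through whichever direction of the pair consumes the surplus —
a one-unknown integer balancing problem with weight-1 arcs.  Undoing a
parallel merge or a cleanup assigns the removed vertices coefficient zero.
The result is asserted to satisfy `C·y = 0` on the original net; an
unbalanceable expansion raises an error rather than guessing.  Note the
expansion maps reduced TIs into original TIs; it is not surjective — a
minimal TI of the original net may have no minimal pre-image (the branching
example's `t1 + t4 + t5` is exactly such a case).

## Synthetic nets

The generator emulates the gross architecture of a curated metabolic
model: `n_pathways` linear input → chain → output pathways (defaults: 3
pathways of 3–6 reactions, the scale at which every analysis including the
exhaustive cross-checks runs in milliseconds), with probability 0.2 of an
internal place being shared with an earlier pathway (branch points),
probability 0.3 of a reaction carrying a `_f`/`_b` backward twin (trivial
TIs), and optionally weight-2 balanced reactions to exercise the weight-1
exclusions of the reduction rules.  Every pathway's indicator vector is a
TI and twins are covered by their trivial TIs, so generated nets are CTI by
construction — which is what makes them useful as ground truth for the
preservation tests.

What the generator does *not* emulate: hub metabolites of very high degree
(ATP-like cofactors), read arcs, unbalanced stoichiometry, and disconnected
or non-CTI defect nets.  Passing the preservation and oracle tests on these
nets therefore demonstrates correctness of the algorithms on well-formed
pathway-structured models, not robustness to arbitrary curation errors;
defect cases (weight exclusions, impure nets, uncovered transitions) are
exercised by dedicated hand-built tests instead.

## Numerical and degenerate-input choices

* All invariant arithmetic is exact integers; there are no tolerances.
* The zero vector is not an invariant; empty invariant sets are valid
  outputs (a net with no PIs is the common case for open metabolic nets).
* Coverage of an empty transition set is vacuously true and flagged as such
  in the CLI summary.
* The deadlock probe is explicit-state BFS with a state cap; on unbounded
  nets it reports "undecided at bound", never deadlock-freeness.
* Markings on deleted connecting/boundary places are dropped by the
  respective reductions (metabolic models start token-free; the ITP merge,
  the only rule the literature specifies marking behaviour for, adds them).
* Ids are free UTF-8 strings; numeric metabolite codes are ordinary ids.

## Known limitations

* Invariant enumeration does not scale to genome-scale models; the intended
  workflow is reduce first, enumerate second, expand the survivors.
* Reduced-net TI sets depend on the (fixed) reduction order in general;
  only the CTI verdict and expansion soundness are order-independent
  claims.
* No SBML import/export; PNML and the reaction table are the two formats.
* Timed, coloured, stochastic and continuous net semantics are out of
  scope, as is full reachability analysis beyond the bounded probe.
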