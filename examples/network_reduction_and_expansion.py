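"""CTI-preserving reduction of the branching example net, then expansion.

The reversible pair t2/t3 between places p1 and p2 is an invariant transition
pair (ITP): both transitions and one place are deleted, the surviving place
absorbs the other's arcs.  TIs of the reduced net map back to TIs of the
original net through the reduction log.
"""

from petrimet import expand_t_invariant, fig5_net, minimal_t_invariants, reduce_net

net = fig5_net()
print(f"original: {len(net.places)} places, {len(net.transitions)} transitions")
for y in minimal_t_invariants(net):
    print("  original TI:", y.render())

reduced, log = reduce_net(net)
print(f"reduced:  {len(reduced.places)} places, {len(reduced.transitions)} transitions")
for ev in log.events:
    print(f"  step {ev.step}: {ev.kind} removed {ev.removed} -> {ev.survivor}")
print("  merged inbound arc weight:",
      reduced.arcs[("t1", log.events[0].survivor)])

for y in minimal_t_invariants(reduced):
    expanded = expand_t_invariant(log, y)
    print(f"  reduced TI {y.render():12s} expands to {expanded.render()}")

# The reduced net keeps only two minimal TIs; each expansion re-inserts the
# one firing of the removed reversible transition needed to rebalance the
# un-merged places, and is verified to satisfy C.y = 0 on the original net.
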