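# File formats

## PNML (ISO 15909-2, P/T subset)

One `<net>` per file, any nesting of `<page>` elements.  Supported:

* `<place id="...">` with optional `<initialMarking><text>N</text></initialMarking>`;
* `<transition id="..."/>`;
* `<arc source="..." target="...">` with optional
  `<inscription><text>W</text></inscription>` (default weight 1);
* a `<toolspecific tool="petrimet" version="1">` block inside a place may
  carry `<capacity>K</capacity>` and/or `<logical canonical="PID"/>`.

A place marked `logical` is a layout copy: on read its arcs and marking are
folded into the canonical place and the merge is recorded in
`PetriNet.logical_groups`.  Reference nodes (`referencePlace`,
`referenceTransition`), non-integer inscriptions, arcs between two vertices
of the same type, and arcs to unknown ids are rejected with a diagnostic
naming the offending element and source line.  The writer emits sorted ids
and is byte-stable; it does not re-split logical copies.

## Reaction-table TSV

UTF-8, tab-separated, header required:

```
id	substrates	products	reversible	boundary
```

* `substrates` / `products`: `+`-joined terms `COEFF*NAME` with `COEFF`
  a positive integer defaulting to 1 (`2*A + B`); empty cell = no terms.
* `reversible`: `rev` or `irr`.  A `rev` record expands to the transition
  pair `ID_f` / `ID_b` with mirrored arcs; the writer collapses such pairs
  back into one `rev` row.
* `boundary`: `input` (substrates must be empty), `output` (products must
  be empty), or `internal`.

Validation collects all offending rows — duplicate ids, non-positive
coefficients, empty both sides, bad flags — and reports them together with
their row numbers (the header is row 1).

## Report files

`write_reports` produces, per analysis:

* `t_invariants.tsv` / `t_invariants.json` — one row per minimal TI:
  id (`TI1`, ...), class, rendered terms (`t1 + t2 + 4*t3`);
* `p_invariants.tsv` — same shape for PIs;
* `ti_classes.tsv` — class counts with fixed row order
  All / trivial / INOUT / IN / OUT / CYC;
* `mct_sets.tsv` — set id, size, `+`-joined members, number of TIs in the
  shared signature; the `uncovered` pseudo-class is the flagged last row;
* `reduction_log.tsv` — step, kind (CTP/ITP/PARALLEL/CLEANUP), removed ids,
  surviving id before and after renaming.

All report writers sort their inputs and are byte-stable given fixed inputs.
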