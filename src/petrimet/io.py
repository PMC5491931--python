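"""Readers and writers: PNML, reaction-table TSV, and analysis reports.

PNML (ISO 15909-2, P/T subset) is the interchange format: places with initial
markings, transitions, weighted arcs.  Capacities and logical place copies are
carried in a ``toolspecific`` annotation; logical copies are merged into their
canonical place on read, so analysis never sees duplicates.

The reaction table is the tabular native format: one reaction per row with
``id``, ``substrates``, ``products`` (terms like ``2*A + B``), ``reversible``
(``rev``/``irr``) and ``boundary`` (``input``/``output``/``internal``)
columns.  A reversible record expands to a ``_f``/``_b`` transition pair on
import, which the invariant classifier recognizes as a split reversible
reaction.  Full grammar in docs/formats.md.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

from lxml import etree

from .core import PetriNet, PetriNetError
from .invariants import InvariantVector

__all__ = [
    "ParseError",
    "TableValidationError",
    "read_pnml",
    "write_pnml",
    "read_reaction_table",
    "write_reaction_table",
    "read_net",
    "write_invariants_tsv",
    "write_invariants_json",
    "write_class_table",
    "write_mct_tsv",
    "write_reduction_log_tsv",
    "write_reports",
]

PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"
PT_TYPE = "http://www.pnml.org/version-2009/grammar/ptnet"
TOOL_NAME = "petrimet"


class ParseError(PetriNetError, ValueError):
    """Malformed or unsupported input file; the message carries a location."""


class TableValidationError(ParseError):
    """Invalid reaction-table rows; the message lists the row numbers."""


# ---------------------------------------------------------------------------
# PNML


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname


def _text_of(el: etree._Element | None) -> str | None:
    if el is None:
        return None
    for child in el:
        if _local(child) == "text":
            return (child.text or "").strip()
    return None


def _loc(el: etree._Element) -> str:
    return f"line {el.sourceline}" if el.sourceline else "unknown location"


_SUPPORTED = {
    "place",
    "transition",
    "arc",
    "page",
    "name",
    "toolspecific",
    "graphics",
}


def read_pnml(path: str | Path) -> PetriNet:
    """Read a P/T net from PNML; logical place copies are merged on read.

    Unsupported PNML features (reference nodes, non-integer inscriptions,
    arcs between two vertices of the same type) are rejected with a named
    diagnostic including the source line.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    nets = [el for el in root.iter() if _local(el) == "net"]
    if len(nets) != 1:
        raise ParseError(f"{path}: expected exactly one <net>, found {len(nets)}")
    net_el = nets[0]

    places: set[str] = set()
    transitions: set[str] = set()
    arcs: dict[tuple[str, str], int] = {}
    capacities: dict[str, int] = {}
    marking: dict[str, int] = {}
    canonical: dict[str, str] = {}  # copy id -> canonical id

    def walk(container: etree._Element) -> None:
        for el in container:
            if not isinstance(el.tag, str):
                continue
            tag = _local(el)
            if tag in ("referencePlace", "referenceTransition"):
                raise ParseError(
                    f"{path}: unsupported PNML feature <{tag}> at {_loc(el)}"
                )
            if tag == "page":
                walk(el)
                continue
            if tag == "place":
                pid = el.get("id")
                if pid is None:
                    raise ParseError(f"{path}: place without id at {_loc(el)}")
                places.add(pid)
                for child in el:
                    ctag = _local(child)
                    if ctag == "initialMarking":
                        txt = _text_of(child)
                        try:
                            marking[pid] = int(txt or "0")
                        except ValueError:
                            raise ParseError(
                                f"{path}: non-integer initial marking {txt!r} "
                                f"at {_loc(child)}"
                            ) from None
                    elif ctag == "toolspecific" and child.get("tool") == TOOL_NAME:
                        for anno in child:
                            atag = _local(anno)
                            if atag == "capacity":
                                capacities[pid] = int(anno.text or "0")
                            elif atag == "logical":
                                canonical[pid] = anno.get("canonical", pid)
            elif tag == "transition":
                tid = el.get("id")
                if tid is None:
                    raise ParseError(f"{path}: transition without id at {_loc(el)}")
                transitions.add(tid)
            elif tag == "arc":
                src, tgt = el.get("source"), el.get("target")
                if src is None or tgt is None:
                    raise ParseError(f"{path}: arc missing endpoint at {_loc(el)}")
                weight = 1
                for child in el:
                    if _local(child) == "inscription":
                        txt = _text_of(child)
                        try:
                            weight = int(txt or "1")
                        except ValueError:
                            raise ParseError(
                                f"{path}: non-integer inscription {txt!r} "
                                f"at {_loc(child)}"
                            ) from None
                arcs[(src, tgt)] = arcs.get((src, tgt), 0) + weight

    walk(net_el)

    # resolve logical copies: redirect arcs, sum markings
    logical_groups: dict[str, str] = {}
    for copy_id, canon in canonical.items():
        if canon == copy_id:
            continue
        if canon not in places:
            raise ParseError(
                f"{path}: logical copy {copy_id!r} references unknown canonical "
                f"place {canon!r}"
            )
        places.discard(copy_id)
        marking[canon] = marking.get(canon, 0) + marking.pop(copy_id, 0)
        redirected: dict[tuple[str, str], int] = {}
        for (u, v), w in arcs.items():
            u2 = canon if u == copy_id else u
            v2 = canon if v == copy_id else v
            redirected[(u2, v2)] = redirected.get((u2, v2), 0) + w
        arcs = redirected
        logical_groups[copy_id] = canon

    for (u, v) in arcs:
        same_type = (u in places and v in places) or (
            u in transitions and v in transitions
        )
        unknown = [x for x in (u, v) if x not in places and x not in transitions]
        if unknown:
            raise ParseError(f"{path}: arc ({u}, {v}) references unknown id {unknown[0]!r}")
        if same_type:
            raise ParseError(
                f"{path}: arc ({u}, {v}) connects two vertices of the same type"
            )

    return PetriNet(
        places=places,
        transitions=transitions,
        arcs=arcs,
        capacities=capacities,
        initial_marking={p: m for p, m in marking.items() if m},
        logical_groups=logical_groups,
        name=net_el.get("id") or Path(path).stem,
    )


def write_pnml(net: PetriNet, path: str | Path) -> None:
    """Write the net as PNML; byte-stable for a given net (sorted ids)."""
    nsmap = {None: PNML_NS}
    root = etree.Element(f"{{{PNML_NS}}}pnml", nsmap=nsmap)
    net_el = etree.SubElement(
        root, f"{{{PNML_NS}}}net", id=net.name or "net", type=PT_TYPE
    )
    page = etree.SubElement(net_el, f"{{{PNML_NS}}}page", id="page0")
    for p in net.sorted_places:
        pel = etree.SubElement(page, f"{{{PNML_NS}}}place", id=p)
        m = net.initial_marking.get(p, 0)
        if m:
            mel = etree.SubElement(pel, f"{{{PNML_NS}}}initialMarking")
            etree.SubElement(mel, f"{{{PNML_NS}}}text").text = str(m)
        if p in net.capacities:
            ts = etree.SubElement(
                pel, f"{{{PNML_NS}}}toolspecific", tool=TOOL_NAME, version="1"
            )
            etree.SubElement(ts, f"{{{PNML_NS}}}capacity").text = str(
                net.capacities[p]
            )
    for t in net.sorted_transitions:
        etree.SubElement(page, f"{{{PNML_NS}}}transition", id=t)
    for i, ((u, v), w) in enumerate(sorted(net.arcs.items())):
        ael = etree.SubElement(
            page, f"{{{PNML_NS}}}arc", id=f"a{i}", source=u, target=v
        )
        if w != 1:
            iel = etree.SubElement(ael, f"{{{PNML_NS}}}inscription")
            etree.SubElement(iel, f"{{{PNML_NS}}}text").text = str(w)
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )


# ---------------------------------------------------------------------------
# reaction-table TSV

TABLE_COLUMNS = ["id", "substrates", "products", "reversible", "boundary"]


def _parse_terms(cell: str, row: int, errors: list[str]) -> list[tuple[str, int]]:
    cell = cell.strip()
    if not cell:
        return []
    terms = []
    for raw in cell.split("+"):
        raw = raw.strip()
        if "*" in raw:
            coeff_s, name = raw.split("*", 1)
            try:
                coeff = int(coeff_s.strip())
            except ValueError:
                errors.append(f"row {row}: bad coefficient in term {raw!r}")
                continue
        else:
            coeff, name = 1, raw
        name = name.strip()
        if coeff < 1:
            errors.append(f"row {row}: non-positive coefficient in term {raw!r}")
            continue
        if not name:
            errors.append(f"row {row}: empty metabolite name in term {raw!r}")
            continue
        terms.append((name, coeff))
    return terms


def read_reaction_table(path: str | Path) -> PetriNet:
    """Build a net from a reaction table.

    Each irreversible record becomes one transition; a reversible record
    becomes a ``_f``/``_b`` pair; a boundary ``input`` record must have no
    substrates (``output``: no products).  Invalid rows are collected and
    reported together with their row numbers.
    """
    places: set[str] = set()
    transitions: set[str] = set()
    arcs: dict[tuple[str, str], int] = {}
    errors: list[str] = []
    seen_ids: set[str] = set()

    def add_reaction(tid: str, subs, prods, row: int) -> None:
        if tid in transitions:
            errors.append(f"row {row}: duplicate reaction id {tid!r}")
            return
        transitions.add(tid)
        for name, coeff in subs:
            places.add(name)
            arcs[(name, tid)] = coeff
        for name, coeff in prods:
            places.add(name)
            arcs[(tid, name)] = coeff

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return PetriNet(name=Path(path).stem)
        missing = [c for c in TABLE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TableValidationError(
                f"{path}: missing columns {missing}; expected {TABLE_COLUMNS}"
            )
        for i, rec in enumerate(reader, start=2):  # row 1 is the header
            rid = (rec["id"] or "").strip()
            if not rid:
                errors.append(f"row {i}: empty reaction id")
                continue
            if rid in seen_ids:
                errors.append(f"row {i}: duplicate reaction id {rid!r}")
                continue
            seen_ids.add(rid)
            subs = _parse_terms(rec["substrates"] or "", i, errors)
            prods = _parse_terms(rec["products"] or "", i, errors)
            rev = (rec["reversible"] or "irr").strip().lower()
            boundary = (rec["boundary"] or "internal").strip().lower()
            if rev not in ("rev", "irr"):
                errors.append(f"row {i}: reversible flag must be 'rev' or 'irr'")
                continue
            if boundary not in ("input", "output", "internal"):
                errors.append(
                    f"row {i}: boundary must be input/output/internal, got {boundary!r}"
                )
                continue
            if not subs and not prods:
                errors.append(f"row {i}: reaction {rid!r} has empty both sides")
                continue
            if boundary == "input" and subs:
                errors.append(f"row {i}: input reaction {rid!r} must have no substrates")
                continue
            if boundary == "output" and prods:
                errors.append(f"row {i}: output reaction {rid!r} must have no products")
                continue
            if rev == "rev":
                add_reaction(rid + "_f", subs, prods, i)
                add_reaction(rid + "_b", prods, subs, i)
            else:
                add_reaction(rid, subs, prods, i)

    if errors:
        raise TableValidationError(f"{path}: " + "; ".join(errors))
    return PetriNet(
        places=places, transitions=transitions, arcs=arcs, name=Path(path).stem
    )


def _render_terms(terms: Sequence[tuple[str, int]]) -> str:
    return " + ".join(
        (f"{c}*{n}" if c != 1 else n) for n, c in sorted(terms)
    )


def write_reaction_table(net: PetriNet, path: str | Path) -> None:
    """Write the net as a reaction table.

    ``_f``/``_b`` transition pairs with mirrored arcs collapse back into one
    reversible record, so read(write(net)) reproduces the net.
    """
    def arcs_of(t: str):
        subs = [(p, net.weight(p, t)) for p in sorted(net.pre_set(t))]
        prods = [(p, net.weight(t, p)) for p in sorted(net.post_set(t))]
        return subs, prods

    def mirrored(t: str, twin: str) -> bool:
        subs, prods = arcs_of(t)
        twin_subs, twin_prods = arcs_of(twin)
        return twin_subs == prods and twin_prods == subs

    rows: list[dict[str, str]] = []
    for t in net.sorted_transitions:
        if t.endswith("_b") and t[:-2] + "_f" in net.transitions and mirrored(
            t, t[:-2] + "_f"
        ):
            continue  # emitted by the _f member of the pair
        subs, prods = arcs_of(t)
        rid, rev = t, "irr"
        if t.endswith("_f"):
            twin = t[:-2] + "_b"
            if twin in net.transitions and mirrored(t, twin):
                rid, rev = t[:-2], "rev"
        boundary = "internal"
        if not subs:
            boundary = "input"
        elif not prods:
            boundary = "output"
        rows.append(
            {
                "id": rid,
                "substrates": _render_terms(subs),
                "products": _render_terms(prods),
                "reversible": rev,
                "boundary": boundary,
            }
        )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=TABLE_COLUMNS, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_net(path: str | Path, fmt: str = "auto") -> PetriNet:
    """Dispatch on format: ``pnml``, ``tsv``, or ``auto`` (by extension)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "pnml" if path.suffix.lower() in (".pnml", ".xml") else "tsv"
    if fmt == "pnml":
        return read_pnml(path)
    if fmt == "tsv":
        return read_reaction_table(path)
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# reports


def _inv_rows(invs: Sequence[InvariantVector], classes: Sequence[str] | None):
    for i, iv in enumerate(invs):
        yield {
            "id": f"{'TI' if iv.kind == 'transition' else 'PI'}{i + 1}",
            "class": classes[i] if classes else "",
            "terms": iv.render(),
        }


def write_invariants_tsv(
    invs: Sequence[InvariantVector],
    path: str | Path,
    classes: Sequence[str] | None = None,
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "class", "terms"], delimiter="\t")
        writer.writeheader()
        writer.writerows(_inv_rows(invs, classes))


def write_invariants_json(
    invs: Sequence[InvariantVector],
    path: str | Path,
    classes: Sequence[str] | None = None,
) -> None:
    data = [
        {
            "id": row["id"],
            "kind": iv.kind,
            "class": row["class"],
            "coeffs": dict(iv.entries),
        }
        for iv, row in zip(invs, _inv_rows(invs, classes))
    ]
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def write_class_table(counts: Mapping[str, int], path: str | Path) -> None:
    """TI class-count table with fixed row order All/trivial/INOUT/IN/OUT/CYC."""
    order = ["All", "trivial", "INOUT", "IN", "OUT", "CYC"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["type", "count"])
        for key in order:
            writer.writerow([key, counts.get(key, 0)])


def write_mct_tsv(partition: Any, path: str | Path) -> None:
    """MCT report: set id, size, member list, TI signature size; the
    uncovered pseudo-class, when present, is the flagged last row."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["set", "size", "members", "n_tis"])
        for i, s in enumerate(partition.sets, start=1):
            writer.writerow(
                [f"MCTS{i}", s.size, "+".join(sorted(s.members)), len(s.ti_signature)]
            )
        if partition.uncovered:
            writer.writerow(
                ["uncovered", len(partition.uncovered), "+".join(sorted(partition.uncovered)), 0]
            )


def write_reduction_log_tsv(log: Any, path: str | Path) -> None:
    """Reduction timescale: step, kind, removed ids, surviving id, new name."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["step", "kind", "removed", "survivor_before", "survivor"],
            delimiter="\t",
        )
        writer.writeheader()
        writer.writerows(log.to_rows())


def write_reports(results: Any, out_dir: str | Path) -> list[Path]:
    """Serialize an analysis-results bundle (see :mod:`petrimet.workflow`)
    into a directory; byte-stable given fixed inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def mark(p: Path) -> Path:
        written.append(p)
        return p

    if results.tis is not None:
        write_invariants_tsv(results.tis, mark(out / "t_invariants.tsv"), results.ti_classes)
        write_invariants_json(results.tis, mark(out / "t_invariants.json"), results.ti_classes)
        write_class_table(results.class_counts, mark(out / "ti_classes.tsv"))
    if results.pis is not None:
        write_invariants_tsv(results.pis, mark(out / "p_invariants.tsv"))
    if results.mct is not None:
        write_mct_tsv(results.mct, mark(out / "mct_sets.tsv"))
    if results.reduction_log is not None:
        write_reduction_log_tsv(results.reduction_log, mark(out / "reduction_log.tsv"))
    return written
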