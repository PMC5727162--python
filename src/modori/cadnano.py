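"""caDNAno-style JSON export/import (honeycomb dialect).

The file carries the standard ``vstrands`` structure — per-helix ``num``,
``row``, ``col``, ``scaf`` and ``stap`` linked-list arrays — plus a
``modori`` metadata block (layout config, staple ids/classes, adjusters)
that makes the round trip exact.  Strand connectivity is always validated
against honeycomb adjacency on import.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

from .design import (
    Adjuster,
    Design,
    DesignError,
    LayoutConfig,
    ModulePartition,
    Staple,
    _build_helices,
    _build_partition,
    _scaffold_index,
    assign_sequences,
    validate_design,
)
from .lattice import are_neighbors

_EMPTY = [-1, -1, -1, -1]


class CadnanoParseError(DesignError):
    """Malformed caDNAno JSON (message carries the location)."""


def _staple_cells(st: Staple) -> list[tuple[int, int]]:
    cells = []
    for (h, s, e), d in zip(st.segments, st.directions):
        xs = range(s, e) if d == 1 else range(e - 1, s - 1, -1)
        cells.extend((h, x) for x in xs)
    return cells


def _chain_arrays(chains: list[list[tuple[int, int]]], lengths: dict[int, int]
                  ) -> dict[int, list[list[int]]]:
    arrays = {h: [list(_EMPTY) for _ in range(n)] for h, n in lengths.items()}
    for chain in chains:
        for i, (h, x) in enumerate(chain):
            prev = chain[i - 1] if i > 0 else (-1, -1)
            nxt = chain[i + 1] if i < len(chain) - 1 else (-1, -1)
            arrays[h][x] = [prev[0], prev[1], nxt[0], nxt[1]]
    return arrays


def export_cadnano(design: Design, path: str | Path) -> None:
    config = design.config
    length = -(-config.bundle_length // 21) * 21  # caDNAno pads to 21
    lengths = {h.helix_id: length for h in design.helices}

    # scaffold: body chain in traversal order, adjuster chain separately
    index = _scaffold_index(design.scaffold_runs, config)
    ordered = sorted(index, key=index.get)
    n_body = config.n_body_helices * config.bundle_length
    scaf = _chain_arrays([ordered[:n_body], ordered[n_body:]], lengths)
    stap = _chain_arrays([_staple_cells(s) for s in design.staples], lengths)

    vstrands = []
    for h in design.helices:
        vstrands.append({
            "num": h.helix_id, "row": h.lattice_row, "col": h.lattice_col,
            "scaf": scaf[h.helix_id], "stap": stap[h.helix_id],
            "loop": [0] * length, "skip": [0] * length,
            "stap_colors": [],
        })
    meta = {
        "name": design.name,
        "config": asdict(config),
        "staples": [{"id": s.staple_id, "cls": s.cls,
                     "segments": [list(seg) for seg in s.segments]}
                    for s in design.staples],
        "adjusters": [asdict(a) for a in design.adjusters],
        "hinge_classes": [list(hc) for hc in design.hinge_classes],
        "module_roles": {m.name: m.role for m in design.partition.modules},
        "scaffold_sequence": design.scaffold_sequence,
    }
    Path(path).write_text(json.dumps(
        {"name": design.name, "vstrands": vstrands, "modori": meta}))


def _trace_chains(arrays: dict[int, list[list[int]]], kind: str
                  ) -> list[list[tuple[int, int]]]:
    """Follow linked lists from their 5' ends; error on malformed links."""
    chains = []
    visited: set[tuple[int, int]] = set()
    for h, arr in sorted(arrays.items()):
        for x, entry in enumerate(arr):
            if entry == _EMPTY:
                continue
            ph, px, _, _ = entry
            if ph != -1:
                continue  # not a 5' end
            chain = []
            cur = (h, x)
            while cur != (-1, -1):
                if cur in visited:
                    raise CadnanoParseError(
                        f"{kind} strand revisits helix {cur[0]} base {cur[1]}")
                visited.add(cur)
                chain.append(cur)
                ch, cx = cur
                try:
                    _, _, nh, nx = arrays[ch][cx]
                except (KeyError, IndexError):
                    raise CadnanoParseError(
                        f"{kind} strand leaves the grid at helix {ch} "
                        f"base {cx}") from None
                cur = (nh, nx)
            chains.append(chain)
    n_cells = sum(1 for arr in arrays.values() for e in arr if e != _EMPTY)
    if sum(len(c) for c in chains) != n_cells:
        raise CadnanoParseError(f"{kind} arrays contain a cycle or orphan link")
    return chains


def _cells_to_segments(cells: list[tuple[int, int]]
                       ) -> tuple[tuple[tuple[int, int, int], ...], tuple[int, ...]]:
    segments, directions = [], []
    run = [cells[0]]
    for c in cells[1:]:
        if c[0] == run[-1][0] and abs(c[1] - run[-1][1]) == 1:
            run.append(c)
        else:
            segments.append(run)
            run = [c]
    segments.append(run)
    segs, dirs = [], []
    for seg in segments:
        xs = [x for _, x in seg]
        d = 1 if len(xs) == 1 or xs[1] > xs[0] else -1
        segs.append((seg[0][0], min(xs), max(xs) + 1))
        dirs.append(d)
    return tuple(segs), tuple(dirs)


def import_cadnano(path: str | Path) -> Design:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise CadnanoParseError(
            f"{path}: invalid JSON at line {exc.lineno} column {exc.colno}"
        ) from exc
    try:
        vstrands = doc["vstrands"]
        meta = doc["modori"]
    except KeyError as exc:
        raise CadnanoParseError(f"{path}: missing top-level key {exc}") from exc

    positions = {v["num"]: (v["row"], v["col"]) for v in vstrands}
    scaf = {v["num"]: v["scaf"] for v in vstrands}
    stap = {v["num"]: v["stap"] for v in vstrands}

    # connectivity validation: crossovers only between honeycomb neighbours
    for kind, arrays in (("scaffold", scaf), ("staple", stap)):
        for h, arr in arrays.items():
            for x, (ph, px, nh, nx) in enumerate(arr):
                for oh in (ph, nh):
                    if oh not in (-1, h) and not are_neighbors(
                            positions[h], positions[oh]):
                        raise CadnanoParseError(
                            f"{kind} crossover between non-neighbour helices "
                            f"{h} and {oh} at base {x}")

    config = LayoutConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in meta["config"].items()})
    helices = _build_helices(config)

    scaf_chains = _trace_chains(scaf, "scaffold")
    adj_id = config.n_helices - 1
    body_chains = [c for c in scaf_chains if c[0][0] != adj_id]
    if len(body_chains) != 1:
        raise CadnanoParseError("expected a single body scaffold strand")
    runs = []
    for (h, s, e), d in zip(*_cells_to_segments(body_chains[0])):
        runs.append((h, s, e, d))

    by_segments = {tuple(tuple(seg) for seg in rec["segments"]): rec
                   for rec in meta["staples"]}
    staples = []
    for chain in _trace_chains(stap, "staple"):
        segs, dirs = _cells_to_segments(chain)
        rec = by_segments.get(segs)
        if rec is None:
            raise CadnanoParseError(
                f"staple with footprint {segs} not in metadata")
        staples.append(Staple(rec["id"], rec["cls"], segs, dirs))
    order = {rec["id"]: i for i, rec in enumerate(meta["staples"])}
    staples.sort(key=lambda s: order[s.staple_id])

    partition = _build_partition(config)
    roles = meta.get("module_roles", {})
    partition = ModulePartition(
        tuple(replace(m, role=roles.get(m.name, m.role))
              for m in partition.modules),
        partition.seams)

    design = Design(
        name=meta["name"], config=config, helices=helices,
        partition=partition, scaffold_runs=tuple(runs),
        staples=tuple(staples),
        adjusters=tuple(Adjuster(**a) for a in meta["adjusters"]),
        hinge_classes=tuple((m, c) for m, c in meta["hinge_classes"]),
    )
    validate_design(design)
    if meta.get("scaffold_sequence"):
        design = assign_sequences(design, meta["scaffold_sequence"])
    return design
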