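"""Module-based design engine for a 12-helix honeycomb origami bundle.

The reference structure is a straight bundle partitioned by scaffold-crossover
seams into nine module regions (L1, L2, L3, M1, M2, M3, R1, R2, R3).  Eleven
body helices carry the folded scaffold; the twelfth lattice helix carries the
adjuster strand, a 504-nt scaffold segment hybridised into duplex form by
strut staples.  Structure modules can be converted into hinges of tunable
stiffness by removing their staples (and optionally re-duplexing a few helices
with hinge staples), and the included angle of a hinged structure is set by
shortening the adjuster on a 21-nt basis, parking the unused scaffold in a
reservoir at the end of the structure.

All edits are local to the touched modules: seam staples are never modified,
so sequence changes cannot propagate along the bundle and variants share the
bulk of the reference staple pool.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import pandas as pd

from .lattice import are_neighbors, default_helix_positions
from .scaffold import reverse_complement

#: axial rise of B-form duplex DNA, nm per base pair
DUPLEX_RISE_NM = 0.34
#: contour length of single-stranded DNA, nm per nucleotide
SINGLE_RISE_NM = 0.63

#: adjuster length of the straight reference design, nt
REFERENCE_ADJUSTER_NT = 504
#: granularity of adjuster-length changes, nt
ADJUSTER_BASIS_NT = 21
#: length of a full strut staple, nt
STRUT_NT = 42
#: number of re-anchoring staples at the reservoir junction of a shortened
#: adjuster (short struts tiled from the junction instead of the 42-nt grid)
ANCHOR_STAPLES = 7

MODULE_NAMES = ("L1", "L2", "L3", "M1", "M2", "M3", "R1", "R2", "R3")
HINGEABLE_MODULES = ("L2", "L3", "M1", "M2", "M3", "R1", "R2")


class DesignError(ValueError):
    """Invalid design construction or edit."""


class BudgetError(DesignError):
    """Scaffold-length budget exceeded."""


@dataclass(frozen=True)
class HingeClass:
    """Hinge cross-section design: how many helices stay double-stranded."""
    name: str
    n_duplex_helices: int
    n_hinge_staples: int


HINGE_CLASSES: dict[str, HingeClass] = {
    name: HingeClass(name, n, n)
    for name, n in [("ds0hb", 0), ("ds2hb", 2), ("ds3hb", 3),
                    ("ds4hb", 4), ("ds6hb", 6)]
}


@dataclass(frozen=True)
class Helix:
    helix_id: int
    lattice_row: int
    lattice_col: int
    length_nt: int
    is_adjuster: bool = False


@dataclass(frozen=True)
class Module:
    name: str
    start: int
    end: int  # half-open
    role: str  # structure | hinge | adjuster

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ModulePartition:
    modules: tuple[Module, ...]
    seams: tuple[tuple[int, int], ...]

    def module(self, name: str) -> Module:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)


@dataclass(frozen=True)
class Staple:
    staple_id: str
    cls: str  # body | seam | strut | hinge
    # ordered footprint segments (helix_id, start, end) with half-open base
    # intervals; traversal within a segment follows `directions` (+1/-1)
    segments: tuple[tuple[int, int, int], ...]
    directions: tuple[int, ...]
    sequence: str = ""

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e in self.segments)


@dataclass(frozen=True)
class Adjuster:
    """One adjuster segment.

    ``side`` is the arm the segment is anchored to: a ``left`` adjuster
    occupies adjuster coordinates [0, length) with its reservoir junction at
    the right end, a ``right`` adjuster occupies [ref - length, ref) with the
    junction at the left end.
    """
    length_nt: int
    duplex_fraction: float = 1.0
    side: str = "left"


@dataclass(frozen=True)
class StapleDiff:
    n_reference: int
    n_replaced: int
    n_removed: int
    n_shared: int

    @property
    def replaced_fraction(self) -> float:
        return self.n_replaced / self.n_reference


@dataclass(frozen=True)
class LayoutConfig:
    """Geometry of the reference bundle (defaults reproduce the 12-helix,
    180-staple reference design)."""
    end_span: int = 63
    middle_spans: tuple[int, ...] = (35, 40, 35, 42, 35, 40, 35)
    seam_span: int = 28
    adjuster_nt: int = REFERENCE_ADJUSTER_NT
    scaffold_length: int = 7249
    n_helices: int = 12
    #: body staples per module (must sum to 108 for the reference layout)
    body_staples: tuple[int, ...] = (15, 11, 12, 11, 11, 11, 11, 11, 15)
    #: seam staples per seam (sum 60)
    seam_staples: tuple[int, ...] = (8, 7, 8, 7, 8, 7, 8, 7)

    @property
    def module_spans(self) -> tuple[int, ...]:
        return (self.end_span, *self.middle_spans, self.end_span)

    @property
    def bundle_length(self) -> int:
        return sum(self.module_spans) + \
            self.seam_span * (len(self.module_spans) - 1)

    @property
    def n_body_helices(self) -> int:
        return self.n_helices - 1

    @property
    def adjuster_start(self) -> int:
        """Bundle coordinate where the adjuster strand begins (anchors are
        symmetric about the bundle midpoint)."""
        return self.bundle_length // 2 - self.adjuster_nt // 2

    @property
    def scaffold_usage(self) -> int:
        """Body + adjuster + reservoir scaffold bases (reservoir counts: it is
        scaffold parked at the end of the structure)."""
        return self.n_body_helices * self.bundle_length + self.adjuster_nt


@dataclass(frozen=True)
class Design:
    name: str
    config: LayoutConfig
    helices: tuple[Helix, ...]
    partition: ModulePartition
    #: scaffold runs (helix_id, start, end, direction), in scaffold order
    scaffold_runs: tuple[tuple[int, int, int, int], ...]
    staples: tuple[Staple, ...]
    adjusters: tuple[Adjuster, ...]
    hinge_classes: tuple[tuple[str, str], ...] = ()  # (module, class name)
    scaffold_sequence: str | None = None

    @property
    def adjuster(self) -> Adjuster:
        return self.adjusters[0]

    @property
    def reservoir_nt(self) -> int:
        return self.config.adjuster_nt - sum(a.length_nt for a in self.adjusters)

    @property
    def body_helices(self) -> tuple[Helix, ...]:
        return tuple(h for h in self.helices if not h.is_adjuster)

    @property
    def adjuster_helix(self) -> Helix:
        return next(h for h in self.helices if h.is_adjuster)

    def staples_of_class(self, cls: str) -> tuple[Staple, ...]:
        return tuple(s for s in self.staples if s.cls == cls)

    def module_staples(self, name: str) -> tuple[Staple, ...]:
        """Staples whose footprint lies entirely within the module's span."""
        m = self.partition.module(name)
        return tuple(
            s for s in self.staples
            if all(m.start <= s0 and e0 <= m.end for _, s0, e0 in s.segments)
        )

    def staple_sequences(self) -> tuple[str, ...]:
        if any(not s.sequence for s in self.staples):
            raise DesignError(
                "design has unsequenced staples; run assign_sequences first")
        return tuple(s.sequence for s in self.staples)


# ---------------------------------------------------------------------------
# unit conversion

def contour_nm(n_bases: int | float, form: str = "duplex") -> float:
    """Contour length in nm of ``n_bases`` of duplex or single-stranded DNA."""
    if n_bases < 0:
        raise ValueError("base count must be non-negative")
    try:
        rise = {"duplex": DUPLEX_RISE_NM, "single": SINGLE_RISE_NM}[form]
    except KeyError:
        raise ValueError(f"unknown form {form!r}") from None
    return n_bases * rise


# ---------------------------------------------------------------------------
# reference construction

def _build_partition(config: LayoutConfig) -> ModulePartition:
    modules, seams = [], []
    x = 0
    spans = config.module_spans
    for i, (name, span) in enumerate(zip(MODULE_NAMES, spans)):
        modules.append(Module(name, x, x + span, "structure"))
        x += span
        if i < len(spans) - 1:
            seams.append((x, x + config.seam_span))
            x += config.seam_span
    if x != config.bundle_length:
        raise DesignError("module/seam spans do not tile the bundle")
    return ModulePartition(tuple(modules), tuple(seams))


def _build_helices(config: LayoutConfig) -> tuple[Helix, ...]:
    positions = default_helix_positions(config.n_helices)
    helices = []
    for i, (r, c) in enumerate(positions):
        is_adj = i == config.n_helices - 1
        length = config.adjuster_nt if is_adj else config.bundle_length
        helices.append(Helix(i, r, c, length, is_adj))
    return tuple(helices)


def _scaffold_runs(config: LayoutConfig,
                   partition: ModulePartition) -> tuple[tuple[int, int, int, int], ...]:
    """Single scaffold traversal of the body grid.

    The bundle is divided into nine blocks, one per module plus half of each
    flanking seam; within a block the scaffold rakes through all body helices
    with antiparallel runs, crossing between consecutive helices at the block
    edges — i.e. inside seam regions, or at the bundle ends where the scaffold
    simply folds back.
    """
    half = config.seam_span // 2
    edges = [0] + [s + half for s, _ in partition.seams] + [config.bundle_length]
    n = config.n_body_helices
    order = list(range(n))
    runs: list[tuple[int, int, int, int]] = []
    for b in range(len(edges) - 1):
        a, bnd = edges[b], edges[b + 1]
        direction = 1
        for h in order:
            if direction == 1:
                runs.append((h, a, bnd, 1))
            else:
                runs.append((h, a, bnd, -1))
            direction = -direction
        order.reverse()
    # merge contiguous same-helix runs (block-to-block continuations)
    merged: list[tuple[int, int, int, int]] = []
    for run in runs:
        if merged:
            h, s, e, d = merged[-1]
            h2, s2, e2, d2 = run
            if h == h2 and d == d2 == 1 and s2 == e:
                merged[-1] = (h, s, e2, 1)
                continue
            if h == h2 and d == d2 == -1 and e2 == s:
                merged[-1] = (h, s2, e, -1)
                continue
        merged.append(run)
    return tuple(merged)


def _scaffold_index(design_or_runs, config: LayoutConfig) -> dict[tuple[int, int], int]:
    """Map body cell (helix, base) -> scaffold position; the adjuster strand
    occupies the positions immediately after the body."""
    runs = design_or_runs
    index: dict[tuple[int, int], int] = {}
    pos = 0
    for h, s, e, d in runs:
        rng = range(s, e) if d == 1 else range(e - 1, s - 1, -1)
        for x in rng:
            index[(h, x)] = pos
            pos += 1
    adj_helix = config.n_helices - 1
    x0 = config.adjuster_start
    for o in range(config.adjuster_nt):
        index[(adj_helix, x0 + o)] = pos
        pos += 1
    return index


def _serpentine_cells(helix_ids: list[int], start: int, end: int
                      ) -> list[tuple[int, int]]:
    cells = []
    for j, h in enumerate(helix_ids):
        xs = range(start, end) if j % 2 == 0 else range(end - 1, start - 1, -1)
        cells.extend((h, x) for x in xs)
    return cells


def _route_region(cells: list[tuple[int, int]], n_staples: int,
                  prefix: str, cls: str) -> list[Staple]:
    """Split a serpentine cell sequence into ``n_staples`` footprints.

    Cut points are spread evenly; a cut that would fall exactly on a helix
    switch is staggered by 14 nt so that staples span crossovers instead of
    ending on them.
    """
    total = len(cells)
    if n_staples < 1 or n_staples > total:
        raise DesignError("staple count out of range for region")
    switches = {i for i in range(1, total) if cells[i - 1][0] != cells[i][0]}
    cuts = [0]
    for i in range(1, n_staples):
        c = round(total * i / n_staples)
        if c in switches:
            c += 14
        if not cuts[-1] < c < total:
            raise DesignError("degenerate staple cut in region routing")
        cuts.append(c)
    cuts.append(total)
    staples = []
    for k in range(n_staples):
        chunk = cells[cuts[k]:cuts[k + 1]]
        segments, directions = [], []
        for h, grp in itertools.groupby(chunk, key=lambda c: c[0]):
            xs = [x for _, x in grp]
            d = 1 if len(xs) == 1 or xs[1] > xs[0] else -1
            segments.append((h, min(xs), max(xs) + 1))
            directions.append(d)
        staples.append(Staple(f"{prefix}:{k}", cls,
                              tuple(segments), tuple(directions)))
    return staples


def _adjuster_staples(config: LayoutConfig,
                      adjusters: tuple[Adjuster, ...]) -> list[Staple]:
    """Strut staples for the current adjuster configuration.

    The full-length reference adjuster is tiled by twelve 42-nt struts on a
    fixed grid.  A shortened adjuster keeps as much of that grid as possible
    (those staples keep their reference sequences) but is re-anchored at its
    reservoir junction by a block of seven short struts whose footprints are
    tied to the junction position — these are the staples a length change
    actually replaces.
    """
    ref = config.adjuster_nt
    x0 = config.adjuster_start
    adj_helix = config.n_helices - 1
    staples: list[Staple] = []

    def strut(offset: int, length: int, sid: str) -> Staple:
        return Staple(sid, "strut",
                      ((adj_helix, x0 + offset, x0 + offset + length),),
                      (1,))

    for adj in adjusters:
        d = int(round(adj.length_nt * adj.duplex_fraction / ADJUSTER_BASIS_NT)
                ) * ADJUSTER_BASIS_NT
        d = max(0, min(adj.length_nt, d))
        tag = adj.side
        if d == 0:
            continue
        if adj.side == "left":
            if d == ref:  # straight reference: full 42-nt strut grid
                for i in range(ref // STRUT_NT):
                    staples.append(strut(i * STRUT_NT, STRUT_NT,
                                         f"strut:{tag}:{i}"))
                continue
            if d >= ANCHOR_STAPLES * ADJUSTER_BASIS_NT:
                grid = STRUT_NT * ((d - 126) // STRUT_NT)
            else:
                grid = 0
            for i in range(grid // STRUT_NT):
                staples.append(strut(i * STRUT_NT, STRUT_NT,
                                     f"strut:{tag}:{i}"))
            block = d - grid
            n_anchor = ANCHOR_STAPLES if block >= ANCHOR_STAPLES * 18 \
                else max(1, block // ADJUSTER_BASIS_NT)
            for k in range(n_anchor):
                o1 = grid + round(block * k / n_anchor)
                o2 = grid + round(block * (k + 1) / n_anchor)
                staples.append(strut(o1, o2 - o1, f"strut:{tag}:anchor:{k}"))
        elif adj.side == "right":
            lo = ref - d
            # junction is at `lo`; the grid-aligned tail keeps reference struts
            aligned = -(-(lo + 126) // STRUT_NT) * STRUT_NT
            if d < ANCHOR_STAPLES * ADJUSTER_BASIS_NT:
                aligned = ref
            block = aligned - lo
            n_anchor = ANCHOR_STAPLES if block >= ANCHOR_STAPLES * 18 \
                else max(1, block // ADJUSTER_BASIS_NT)
            for k in range(n_anchor):
                o1 = lo + round(block * k / n_anchor)
                o2 = lo + round(block * (k + 1) / n_anchor)
                staples.append(strut(o1, o2 - o1, f"strut:{tag}:anchor:{k}"))
            for o in range(aligned, ref, STRUT_NT):
                staples.append(strut(o, STRUT_NT, f"strut:{tag}:{o // STRUT_NT}"))
        else:
            raise DesignError(f"unknown adjuster side {adj.side!r}")
    return staples


def _module_body_staples(config: LayoutConfig, partition: ModulePartition,
                         name: str) -> list[Staple]:
    m = partition.module(name)
    idx = MODULE_NAMES.index(name)
    n = config.body_staples[idx]
    helix_ids = list(range(config.n_body_helices))
    cells = _serpentine_cells(helix_ids, m.start, m.end)
    return _route_region(cells, n, f"body:{name}", "body")


def build_reference(config: LayoutConfig | None = None) -> Design:
    """Build the straight reference design.

    With the default layout this yields 180 staples (108 body, 60 seam, 12
    strut), nine modules, and a fully duplexed 504-nt adjuster with an empty
    reservoir.
    """
    config = config or LayoutConfig()
    if config.scaffold_usage > config.scaffold_length:
        raise BudgetError(
            f"layout needs {config.scaffold_usage} scaffold bases but the "
            f"scaffold has only {config.scaffold_length}")
    partition = _build_partition(config)
    helices = _build_helices(config)
    runs = _scaffold_runs(config, partition)

    staples: list[Staple] = []
    for name in MODULE_NAMES:
        staples.extend(_module_body_staples(config, partition, name))
    helix_ids = list(range(config.n_body_helices))
    for i, ((s, e), n) in enumerate(zip(partition.seams, config.seam_staples)):
        cells = _serpentine_cells(helix_ids, s, e)
        staples.extend(_route_region(cells, n, f"seam:{i}", "seam"))
    adjusters = (Adjuster(config.adjuster_nt, 1.0, "left"),)
    staples.extend(_adjuster_staples(config, adjusters))

    design = Design("reference", config, helices, partition, runs,
                    tuple(staples), adjusters)
    validate_design(design)
    return design


# ---------------------------------------------------------------------------
# validation

def validate_design(design: Design) -> None:
    """Assert the structural invariants; raise DesignError on violation."""
    config = design.config
    helix_by_id = {h.helix_id: h for h in design.helices}
    pos = {(h.lattice_row, h.lattice_col): h.helix_id for h in design.helices}
    if len(pos) != len(design.helices):
        raise DesignError("duplicate lattice positions")

    # honeycomb adjacency of consecutive scaffold runs + single full traversal
    seen: set[tuple[int, int]] = set()
    prev = None
    seam_set = design.partition.seams
    for h, s, e, d in design.scaffold_runs:
        cells = [(h, x) for x in range(s, e)]
        if seen.intersection(cells):
            raise DesignError("scaffold visits a base twice")
        seen.update(cells)
        if prev is not None:
            ph, px = prev
            x = s if d == 1 else e - 1
            if h == ph:
                # same-helix continuation into the next block, no crossover
                if abs(x - px) != 1:
                    raise DesignError("scaffold run discontinuity")
                prev = (h, e - 1) if d == 1 else (h, s)
                continue
            if x != px:
                raise DesignError("scaffold crossover is not vertical")
            a, b = helix_by_id[ph], helix_by_id[h]
            if not are_neighbors((a.lattice_row, a.lattice_col),
                                 (b.lattice_row, b.lattice_col)):
                raise DesignError("scaffold crossover between non-neighbours")
            at_end = x in (0, config.bundle_length - 1)
            in_seam = any(s0 <= x < e0 for s0, e0 in seam_set)
            if not (at_end or in_seam):
                raise DesignError(
                    f"scaffold crossover at base {x} outside seam regions")
        prev = (h, e - 1) if d == 1 else (h, s)
    n_body_cells = config.n_body_helices * config.bundle_length
    if len(seen) != n_body_cells:
        raise DesignError("scaffold does not cover every body base")

    # staple occupancy and crossover validity
    occupied: set[tuple[int, int]] = set()
    for st in design.staples:
        for i, (h, s, e) in enumerate(st.segments):
            if h not in helix_by_id:
                raise DesignError(f"staple {st.staple_id} on unknown helix")
            cells = {(h, x) for x in range(s, e)}
            if occupied & cells:
                raise DesignError(
                    f"staple {st.staple_id} overlaps another staple")
            occupied |= cells
            if i > 0:
                a = helix_by_id[st.segments[i - 1][0]]
                b = helix_by_id[h]
                if not are_neighbors((a.lattice_row, a.lattice_col),
                                     (b.lattice_row, b.lattice_col)):
                    raise DesignError(
                        f"staple {st.staple_id} crossover between "
                        "non-neighbour helices")

    # partition tiling
    covered = []
    for m in design.partition.modules:
        covered.append((m.start, m.end))
    covered.extend(design.partition.seams)
    covered.sort()
    x = 0
    for s, e in covered:
        if s != x or e <= s:
            raise DesignError("modules and seams do not tile the bundle")
        x = e
    if x != config.bundle_length:
        raise DesignError("modules and seams do not tile the bundle")

    # scaffold budget (body + adjuster + reservoir)
    if config.scaffold_usage > config.scaffold_length:
        raise BudgetError("scaffold budget exceeded")
    if design.reservoir_nt < 0:
        raise BudgetError("adjusters exceed the reference adjuster length")


# ---------------------------------------------------------------------------
# design edits

def partition_modules(design: Design) -> ModulePartition:
    """The design's seam-bounded module partition (validated)."""
    validate_design(design)
    return design.partition


def _hinge_helix_ranking(design: Design) -> list[int]:
    """Body helices ordered by distance from the cross-section centroid
    (symmetric hinge-staple placement), ties broken by helix id."""
    body = design.body_helices
    r0 = sum(h.lattice_row for h in body) / len(body)
    c0 = sum(h.lattice_col for h in body) / len(body)
    return [h.helix_id for h in sorted(
        body, key=lambda h: ((h.lattice_row - r0) ** 2 +
                             (h.lattice_col - c0) ** 2, h.helix_id))]


def apply_hinge(design: Design, module_name: str,
                hinge_class: str | HingeClass) -> Design:
    """Turn a structure module into a hinge of the given class.

    All body staples inside the module are removed; for dsNhb with N > 0, N
    hinge staples re-duplex the N helices closest to the cross-section
    centroid.  Seam staples and the scaffold path are untouched.
    """
    hc = HINGE_CLASSES[hinge_class] if isinstance(hinge_class, str) else hinge_class
    if module_name not in HINGEABLE_MODULES:
        raise DesignError(
            f"{module_name!r} is not a hinge-capable structure module")
    m = design.partition.module(module_name)
    removed_ids = {s.staple_id for s in design.module_staples(module_name)
                   if s.cls == "body"}
    staples = [s for s in design.staples if s.staple_id not in removed_ids]
    staples = [s for s in staples
               if not (s.cls == "hinge"
                       and s.staple_id.startswith(f"hinge:{module_name}:"))]
    for h in _hinge_helix_ranking(design)[:hc.n_duplex_helices]:
        staples.append(Staple(f"hinge:{module_name}:{h}", "hinge",
                              ((h, m.start, m.end),), (1,)))
    modules = tuple(replace(mm, role="hinge") if mm.name == module_name else mm
                    for mm in design.partition.modules)
    hinge_classes = tuple(hc_ for hc_ in design.hinge_classes
                          if hc_[0] != module_name) + ((module_name, hc.name),)
    out = replace(design,
                  name=f"{design.name}+{module_name}:{hc.name}",
                  partition=ModulePartition(modules, design.partition.seams),
                  staples=tuple(staples),
                  hinge_classes=hinge_classes,
                  scaffold_sequence=None)
    out = _resequence_if_possible(out, design)
    return out


def fill_module(design: Design, module_name: str) -> Design:
    """Inverse of :func:`apply_hinge`: restore the structure staples."""
    m = design.partition.module(module_name)
    if m.role != "hinge":
        raise DesignError(f"{module_name!r} is not a hinge module")
    staples = [s for s in design.staples
               if not (s.cls == "hinge"
                       and s.staple_id.startswith(f"hinge:{module_name}:"))]
    staples.extend(_module_body_staples(design.config, design.partition,
                                        module_name))
    modules = tuple(replace(mm, role="structure") if mm.name == module_name
                    else mm for mm in design.partition.modules)
    # keep reference staple ordering so the design compares equal
    order = {sid: i for i, sid in enumerate(
        s.staple_id for s in build_reference(design.config).staples)}
    staples.sort(key=lambda s: order.get(s.staple_id, len(order)))
    out = replace(design,
                  name=f"{design.name}-{module_name}",
                  partition=ModulePartition(modules, design.partition.seams),
                  staples=tuple(staples),
                  hinge_classes=tuple(h for h in design.hinge_classes
                                      if h[0] != module_name),
                  scaffold_sequence=None)
    return _resequence_if_possible(out, design)


def set_adjuster(design: Design, length_nt: int,
                 duplex_fraction: float = 1.0) -> Design:
    """Set a single adjuster of the given length; surplus scaffold moves to
    the reservoir and surplus strut staples are eliminated."""
    return set_adjusters(design, (Adjuster(length_nt, duplex_fraction, "left"),))


def set_adjusters(design: Design, adjusters: tuple[Adjuster, ...]) -> Design:
    ref = design.config.adjuster_nt
    total = sum(a.length_nt for a in adjusters)
    for a in adjusters:
        if not 0 < a.length_nt <= ref:
            raise DesignError(
                f"adjuster length {a.length_nt} outside (0, {ref}]")
        if not 0.0 <= a.duplex_fraction <= 1.0:
            raise DesignError("duplex_fraction must lie in [0, 1]")
    if total > ref:
        raise DesignError("adjusters exceed the reference adjuster length")
    sides = [a.side for a in adjusters]
    if len(adjusters) == 2 and sides != ["left", "right"]:
        raise DesignError("double adjusters must be anchored left and right")
    staples = [s for s in design.staples if s.cls != "strut"]
    staples.extend(_adjuster_staples(design.config, adjusters))
    out = replace(design,
                  name=f"{design.name}@adj{'+'.join(str(a.length_nt) for a in adjusters)}",
                  staples=tuple(staples),
                  adjusters=adjusters,
                  scaffold_sequence=None)
    return _resequence_if_possible(out, design)


# ---------------------------------------------------------------------------
# sequences and diffs

def _staple_sequence(st: Staple, index: dict[tuple[int, int], int],
                     scaffold: str) -> str:
    bases = []
    for (h, s, e), d in zip(st.segments, st.directions):
        xs = range(s, e) if d == 1 else range(e - 1, s - 1, -1)
        bases.extend(scaffold[index[(h, x)]] for x in xs)
    return reverse_complement("".join(bases))


def assign_sequences(design: Design, scaffold: str) -> Design:
    """Assign every staple the reverse complement of the scaffold it binds."""
    config = design.config
    if len(scaffold) < config.scaffold_usage:
        raise BudgetError(
            f"scaffold of {len(scaffold)} nt is shorter than the design's "
            f"usage of {config.scaffold_usage} nt")
    index = _scaffold_index(design.scaffold_runs, config)
    staples = tuple(replace(s, sequence=_staple_sequence(s, index, scaffold))
                    for s in design.staples)
    return replace(design, staples=staples, scaffold_sequence=scaffold)


def _resequence_if_possible(out: Design, source: Design) -> Design:
    if source.scaffold_sequence is not None:
        return assign_sequences(out, source.scaffold_sequence)
    return out


def diff_staples(variant: Design, reference: Design) -> StapleDiff:
    """Replacement accounting of a variant against the reference pool.

    ``n_replaced`` counts variant staples whose sequence does not occur in
    the reference pool; ``n_removed`` counts reference staples absent from
    the variant.
    """
    ref_seqs = set(reference.staple_sequences())
    var_seqs = set(variant.staple_sequences())
    n_replaced = sum(1 for s in variant.staples if s.sequence not in ref_seqs)
    n_shared = sum(1 for s in variant.staples if s.sequence in ref_seqs)
    n_removed = sum(1 for s in reference.staples if s.sequence not in var_seqs)
    return StapleDiff(len(reference.staples), n_replaced, n_removed, n_shared)


# ---------------------------------------------------------------------------
# tabular export

def staple_table(design: Design) -> pd.DataFrame:
    rows = []
    for s in design.staples:
        h0, s0, _ = s.segments[0]
        h1, _, e1 = s.segments[-1]
        rows.append({"staple_id": s.staple_id, "class": s.cls,
                     "start_helix": h0, "start_base": s0,
                     "end_helix": h1, "end_base": e1 - 1,
                     "length": s.length, "sequence": s.sequence})
    return pd.DataFrame(rows)
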