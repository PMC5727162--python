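"""The 24-variant demonstration catalog and the included-angle series.

Every variant is produced from the straight reference purely by module edits
(:func:`~modori.design.apply_hinge`) and adjuster-length changes
(:func:`~modori.design.set_adjuster` / :func:`~modori.design.set_adjusters`),
so all of them share the reference staple pool up to a handful of replaced
staples.  Cases 1-8 are single-hinged shapes, cases 9-16 multi-hinged shapes
driven by one adjuster, and cases 17-24 closed-form shapes or shapes with
double/asymmetric adjusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .design import (
    ADJUSTER_BASIS_NT,
    Adjuster,
    Design,
    apply_hinge,
    set_adjuster,
    set_adjusters,
)


@dataclass(frozen=True)
class VariantSpec:
    case: int
    label: str
    hinges: tuple[tuple[str, str], ...]  # (module, hinge class)
    adjusters: tuple[tuple[int, str], ...]  # (length_nt, side)


#: composition of the demonstration catalog (single / multi / complex groups)
CATALOG_SPECS: tuple[VariantSpec, ...] = tuple(
    VariantSpec(i + 1, label, tuple(hinges), tuple(adjusters))
    for i, (label, hinges, adjusters) in enumerate([
        # cases 1-8: one ds0hb hinge, varied location and included angle
        ("single-L2",        [("L2", "ds0hb")], [(357, "left")]),
        ("single-L3",        [("L3", "ds0hb")], [(315, "left")]),
        ("single-M1",        [("M1", "ds0hb")], [(273, "left")]),
        ("single-M2-open",   [("M2", "ds0hb")], [(357, "left")]),
        ("single-M2-closed", [("M2", "ds0hb")], [(252, "left")]),
        ("single-M3",        [("M3", "ds0hb")], [(315, "left")]),
        ("single-R1",        [("R1", "ds0hb")], [(399, "left")]),
        ("single-R2",        [("R2", "ds0hb")], [(441, "left")]),
        # cases 9-16: two or three hinges, one adjuster
        ("double-M1M3",      [("M1", "ds0hb"), ("M3", "ds0hb")], [(336, "left")]),
        ("double-L3R1",      [("L3", "ds0hb"), ("R1", "ds0hb")], [(294, "left")]),
        ("double-M1M3-stiff", [("M1", "ds2hb"), ("M3", "ds2hb")], [(336, "left")]),
        ("triple-L2M2R2",    [("L2", "ds0hb"), ("M2", "ds0hb"), ("R2", "ds0hb")],
         [(252, "left")]),
        ("triple-L3M2R1",    [("L3", "ds0hb"), ("M2", "ds0hb"), ("R1", "ds0hb")],
         [(294, "left")]),
        ("double-mixed",     [("M1", "ds0hb"), ("M2", "ds2hb")], [(315, "left")]),
        ("double-L2R2-stiff", [("L2", "ds2hb"), ("R2", "ds2hb")], [(378, "left")]),
        ("triple-mixed",     [("L3", "ds0hb"), ("M2", "ds2hb"), ("R1", "ds0hb")],
         [(294, "left")]),
        # cases 17-24: closed forms and double/asymmetric adjusters
        ("closed-triangle",  [("M2", "ds0hb")], [(168, "left"), (168, "right")]),
        ("closed-quad",      [("L3", "ds0hb"), ("R1", "ds0hb")],
         [(189, "left"), (189, "right")]),
        ("single-M1-stiff",  [("M1", "ds3hb")], [(294, "left")]),
        ("single-M2-ds4",    [("M2", "ds4hb")], [(294, "left")]),
        ("double-adj-asym",  [("L3", "ds2hb"), ("R1", "ds2hb")],
         [(210, "left"), (168, "right")]),
        ("triple-double-adj", [("M1", "ds2hb"), ("M2", "ds2hb"), ("M3", "ds2hb")],
         [(189, "left"), (168, "right")]),
        ("double-adj-stiff", [("L2", "ds3hb"), ("R2", "ds3hb")],
         [(210, "left"), (210, "right")]),
        ("closed-max",       [("M1", "ds3hb"), ("M2", "ds3hb"), ("M3", "ds3hb")],
         [(168, "left"), (168, "right")]),
    ])
)


def build_variant(reference: Design, spec: VariantSpec) -> Design:
    d = reference
    for module, hc in spec.hinges:
        d = apply_hinge(d, module, hc)
    d = set_adjusters(d, tuple(Adjuster(n, 1.0, side)
                               for n, side in spec.adjusters))
    return d


def build_variant_catalog(reference: Design) -> list[Design]:
    """All 24 demonstration variants, in case order."""
    return [build_variant(reference, spec) for spec in CATALOG_SPECS]


# ---------------------------------------------------------------------------
# included-angle series

def series_lengths(targets_deg: tuple[float, ...] | None = None,
                   reference_nt: int = 504) -> list[int]:
    """Adjuster lengths (21-nt basis) for a series of target included angles.

    With the adjuster anchored symmetrically about the hinge, a duplex
    adjuster of length ``n`` sets the included angle through the chord
    relation ``0.34 n = 2 r sin(theta/2)`` with ``2 r = 0.34 * reference``;
    the nearest multiple of the 21-nt basis is used for each target.
    """
    if targets_deg is None:
        targets_deg = tuple(range(150, -1, -15))
    lengths = []
    for t in targets_deg:
        ideal = reference_nt * math.sin(math.radians(t) / 2)
        n = max(1, round(ideal / ADJUSTER_BASIS_NT)) * ADJUSTER_BASIS_NT
        lengths.append(min(n, reference_nt))
    return lengths


def angle_series(reference: Design, module: str = "M2",
                 hinge_class: str = "ds2hb",
                 targets_deg: tuple[float, ...] | None = None
                 ) -> list[tuple[float, Design]]:
    """The 11-design series spanning included angles 150..0 deg in 15-deg
    steps via 21-nt adjuster changes, with a fixed central hinge."""
    if targets_deg is None:
        targets_deg = tuple(range(150, -1, -15))
    hinged = apply_hinge(reference, module, hinge_class)
    return [(t, set_adjuster(hinged, n))
            for t, n in zip(targets_deg, series_lengths(targets_deg,
                                                        reference.config.adjuster_nt))]
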