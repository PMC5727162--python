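"""Honeycomb-lattice geometry for helix bundles.

DNA bundles packed on the honeycomb lattice have at most three nearest
neighbours per helix: two in-row neighbours and one out-of-row neighbour whose
direction (up or down) alternates with the parity of ``row + col``.  This is
the same convention caDNAno uses for its honeycomb part.
"""

from __future__ import annotations


def honeycomb_neighbors(row: int, col: int) -> list[tuple[int, int]]:
    """Lattice coordinates of the (up to three) honeycomb neighbours.

    The vertical neighbour of ``(row, col)`` is ``(row + 1, col)`` when
    ``row + col`` is odd and ``(row - 1, col)`` when it is even, which makes
    the relation symmetric.
    """
    out = [(row, col - 1), (row, col + 1)]
    if (row + col) % 2 == 1:
        out.append((row + 1, col))
    else:
        out.append((row - 1, col))
    return out


def are_neighbors(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return tuple(b) in honeycomb_neighbors(*a)


def default_helix_positions(n_helices: int = 12) -> list[tuple[int, int]]:
    """Lattice positions for the bundle, ordered along a Hamiltonian path.

    Helices are laid out on two rows of six columns and numbered along a
    serpentine path (row 0 left-to-right, then row 1 right-to-left) so that
    consecutive helix ids are always lattice neighbours.  Helix 11 — the last
    one, at (1, 0) — carries the adjuster strand in the default design.
    """
    if n_helices % 2 != 0:
        raise ValueError("bundle must have an even helix count on two rows")
    half = n_helices // 2
    top = [(0, c) for c in range(half)]
    bottom = [(1, c) for c in reversed(range(half))]
    positions = top + bottom
    # the turn of the serpentine relies on (0, half-1)-(1, half-1) being an
    # edge, i.e. half-1 must be odd
    if not are_neighbors(positions[half - 1], positions[half]):
        raise ValueError("serpentine turn is not a honeycomb edge")
    return positions
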