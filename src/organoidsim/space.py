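"""3D integer lattice with Chebyshev geometry.

The simulation space is a finite cubic grid of integer coordinates with
equal edges.  The minimum displacement moves a coordinate to one of its (up
to) 26 Chebyshev-distance-1 neighbors.  Cell bodies occupy exactly one
coordinate exclusively; axon segments and spatial marks are sizeless
"pass-through" occupants that never block placement or movement.

Conventions: coordinates are 0-based integer triples, bounds are hard walls
(coordinates outside ``[0, edge-1]`` do not exist; no wrap-around).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

Coord = tuple[int, int, int]

#: The 26 unit displacements of the Chebyshev-1 neighborhood, in fixed
#: lexicographic order (determinism of every iteration depends on it).
UNIT_DISPLACEMENTS: tuple[Coord, ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


def chebyshev_distance(a: Coord, b: Coord) -> int:
    """Max over per-axis absolute differences."""
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]), abs(a[2] - b[2]))


@dataclass(frozen=True)
class SpatialMark:
    """Sizeless lattice entity that emits diffusing factors.

    Marks occupy no exclusive space: a coordinate holding a mark stays
    vacant for cell placement.
    """

    id: int
    coordinate: Coord
    emitted_factors: tuple[str, ...] = ()


class Lattice:
    """Occupancy bookkeeping over the cubic grid.

    ``cell_occupancy`` maps a coordinate to the single cell-body object id
    occupying it; ``passthrough_occupancy`` maps a coordinate to the set of
    sizeless occupants (axon segments, spatial marks) resting there.
    """

    def __init__(self, edge: int):
        if edge < 3:
            raise ValueError(f"lattice edge must be >= 3, got {edge}")
        self.edge = int(edge)
        self.cell_occupancy: dict[Coord, int] = {}
        self.passthrough_occupancy: dict[Coord, set[int]] = {}

    def in_bounds(self, c: Coord) -> bool:
        e = self.edge
        return 0 <= c[0] < e and 0 <= c[1] < e and 0 <= c[2] < e

    def is_vacant(self, c: Coord) -> bool:
        """False iff a cell body occupies ``c`` (marks/segments don't count)."""
        return c not in self.cell_occupancy

    def occupant(self, c: Coord) -> int | None:
        return self.cell_occupancy.get(c)

    def place(self, object_id: int, c: Coord) -> None:
        if not self.in_bounds(c):
            raise ValueError(f"coordinate {c} outside lattice of edge {self.edge}")
        if c in self.cell_occupancy:
            raise ValueError(
                f"coordinate {c} already occupied by object "
                f"{self.cell_occupancy[c]}"
            )
        self.cell_occupancy[c] = object_id

    def vacate(self, object_id: int, c: Coord) -> None:
        if self.cell_occupancy.get(c) != object_id:
            raise ValueError(f"object {object_id} does not occupy {c}")
        del self.cell_occupancy[c]

    def add_passthrough(self, object_id: int, c: Coord) -> None:
        self.passthrough_occupancy.setdefault(c, set()).add(object_id)

    def n_cells(self) -> int:
        return len(self.cell_occupancy)


def neighborhood(c: Coord, radius: int, lattice: Lattice) -> list[Coord]:
    """In-bounds coordinates at Chebyshev distance 1..radius from ``c``.

    Excludes ``c`` itself.  Returned in fixed lexicographic order so callers
    drawing random elements replay deterministically.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    e = lattice.edge
    x, y, z = c
    out: list[Coord] = []
    for dx in range(-radius, radius + 1):
        nx = x + dx
        if not 0 <= nx < e:
            continue
        for dy in range(-radius, radius + 1):
            ny = y + dy
            if not 0 <= ny < e:
                continue
            for dz in range(-radius, radius + 1):
                if dx == 0 and dy == 0 and dz == 0:
                    continue
                nz = z + dz
                if 0 <= nz < e:
                    out.append((nx, ny, nz))
    return out


def vacant_neighbors(c: Coord, lattice: Lattice, radius: int = 1) -> list[Coord]:
    return [n for n in neighborhood(c, radius, lattice) if lattice.is_vacant(n)]


def displace(
    lattice: Lattice,
    mover_id: int,
    from_c: Coord,
    to_c: Coord,
    rng: np.random.Generator,
    can_eject=None,
) -> bool:
    """Move ``mover_id`` one unit step, optionally pushing an occupant aside.

    If ``to_c`` is vacant the move simply transfers occupancy.  If it is
    occupied and ``can_eject(occupant_id)`` is true, the occupant is pushed
    to a uniformly chosen vacant neighbor of ``to_c`` (a single-level push:
    ejected objects never eject others), then the mover takes ``to_c``.
    Returns False (state unchanged) when the target is out of bounds,
    blocked by a stationary occupant, or the occupant has nowhere to go.
    """
    if lattice.cell_occupancy.get(from_c) != mover_id:
        raise ValueError(f"mover {mover_id} does not occupy {from_c}")
    if chebyshev_distance(from_c, to_c) != 1:
        raise ValueError("displace only performs unit steps")
    if not lattice.in_bounds(to_c):
        return False
    occupant = lattice.occupant(to_c)
    if occupant is None:
        lattice.vacate(mover_id, from_c)
        lattice.place(mover_id, to_c)
        return True
    if can_eject is None or not can_eject(occupant):
        return False
    spots = vacant_neighbors(to_c, lattice)
    if not spots:
        return False
    spot = spots[int(rng.integers(len(spots)))]
    lattice.vacate(occupant, to_c)
    lattice.place(occupant, spot)
    lattice.vacate(mover_id, from_c)
    lattice.place(mover_id, to_c)
    return True
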