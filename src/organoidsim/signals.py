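"""Extracellular factor fields: secretion, diffusion, degradation, queries.

Each chemical factor lives on its own lattice-sized concentration grid.
Secretion deposits a configured signal power at the source coordinate;
spreading is a truncated discrete-Gaussian convolution applied once per
tick; degradation is multiplicative exponential decay.  A factor is only
meaningful within the union of Chebyshev balls of radius ``emission_radius``
around its past sources (its significant-action support); concentrations
outside that support are forced to zero, which is what keeps fields sparse
and the simulation fast.

The concentration grid is stored densely (one float per lattice voxel) with
a pruning floor that zeroes negligible entries; the sparse-map contract
(unset coordinate reads as 0) is preserved at the API surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .space import Coord, Lattice, neighborhood

#: Concentrations below this are pruned to exactly zero after each update.
PRUNE_FLOOR = 1e-12


@dataclass(frozen=True)
class FactorDef:
    """Static description of one diffusible factor.

    Parameters
    ----------
    emission_radius
        Significant action radius in lattice units; the signal is ignored
        beyond this Chebyshev distance from any source.
    signal_power
        Concentration deposited at the source per secretion event.
    propagation_rate
        Per-tick diffusion strength in [0, 1]; the per-step Gaussian kernel
        has variance ``sigma2 = propagation_rate`` (lattice units squared).
    degradation_rate
        Per-tick fractional decay in [0, 1].
    """

    id: str
    emission_radius: int = 1
    signal_power: float = 1.0
    propagation_rate: float = 0.5
    degradation_rate: float = 0.0

    def __post_init__(self):
        if self.emission_radius < 1:
            raise ValueError(f"{self.id}: emission_radius must be >= 1")
        if not 0.0 <= self.propagation_rate <= 1.0:
            raise ValueError(f"{self.id}: propagation_rate must be in [0,1]")
        if not 0.0 <= self.degradation_rate <= 1.0:
            raise ValueError(f"{self.id}: degradation_rate must be in [0,1]")
        if self.signal_power < 0:
            raise ValueError(f"{self.id}: signal_power must be >= 0")


def _kernel_1d(sigma2: float) -> np.ndarray:
    """Normalized 3-tap discrete Gaussian; collapses to a delta as sigma2->0."""
    if sigma2 <= 0:
        return np.array([0.0, 1.0, 0.0])
    w = math.exp(-1.0 / (2.0 * sigma2))
    k = np.array([w, 1.0, w])
    return k / k.sum()


class FactorField:
    """Concentration map of a single factor over the lattice."""

    def __init__(self, factor: FactorDef, edge: int):
        self.factor = factor
        self.edge = int(edge)
        self.values = np.zeros((edge, edge, edge))
        self.support = np.zeros((edge, edge, edge), dtype=bool)
        self._k1 = _kernel_1d(factor.propagation_rate)
        # inclusive bounding box of the support, or None while empty
        self._lo: np.ndarray | None = None
        self._hi: np.ndarray | None = None

    # -- sources ---------------------------------------------------------

    def secrete(self, source: Coord, power: float | None = None) -> None:
        """Deposit signal power at ``source`` and extend the support ball."""
        p = self.factor.signal_power if power is None else power
        self.values[source] += p
        r = self.factor.emission_radius
        lo = np.maximum(np.array(source) - r, 0)
        hi = np.minimum(np.array(source) + r, self.edge - 1)
        self.support[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = True
        if self._lo is None:
            self._lo, self._hi = lo, hi
        else:
            self._lo = np.minimum(self._lo, lo)
            self._hi = np.maximum(self._hi, hi)

    def _box(self):
        if self._lo is None:
            return None
        lo, hi = self._lo, self._hi
        return tuple(slice(int(lo[i]), int(hi[i]) + 1) for i in range(3))

    # -- per-tick updates ------------------------------------------------

    def diffuse_step(self) -> None:
        """One truncated discrete-Gaussian spreading step.

        The 3x3x3 kernel is separable and sums to one, so total mass is
        conserved except for leakage through the lattice boundary and the
        truncation to the significant-action support.
        """
        box = self._box()
        if box is None or self.factor.propagation_rate <= 0:
            return
        sub = self.values[box]
        if not sub.any():
            return
        for axis in range(3):
            sub = ndimage.correlate1d(sub, self._k1, axis=axis,
                                      mode="constant", cval=0.0)
        sub *= self.support[box]
        sub[sub < PRUNE_FLOOR] = 0.0
        self.values[box] = sub

    def degrade_step(self) -> None:
        """Multiplicative exponential decay: v <- v * (1 - degradation_rate)."""
        d = self.factor.degradation_rate
        if d <= 0:
            return
        box = self._box()
        if box is None:
            return
        sub = self.values[box]
        sub *= (1.0 - d)
        sub[sub < PRUNE_FLOOR] = 0.0

    # -- queries ---------------------------------------------------------

    def concentration_at(self, c: Coord) -> float:
        return float(self.values[c])

    def max_in_ball(self, c: Coord, radius: int) -> float:
        """Max concentration over the Chebyshev ball (center included)."""
        if radius <= 0:
            return float(self.values[c])
        e = self.edge
        lo = [max(c[i] - radius, 0) for i in range(3)]
        hi = [min(c[i] + radius, e - 1) for i in range(3)]
        return float(
            self.values[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1].max()
        )

    def total_mass(self) -> float:
        return float(self.values.sum())

    def nonzero_items(self):
        """Yield ((x, y, z), concentration) for every nonzero voxel."""
        for idx in zip(*np.nonzero(self.values)):
            c = (int(idx[0]), int(idx[1]), int(idx[2]))
            yield c, float(self.values[c])


@dataclass(frozen=True)
class GradientRule:
    """How a mover evaluates candidate coordinates against a factor field.

    ``direction`` selects climbing the gradient or the anti-gradient.  The
    satisfaction predicate is a concentration band every candidate must lie
    in (``min_concentration`` > 0 demands positive signal).
    """

    factor: str
    direction: str = "gradient"  # or "anti-gradient"
    min_concentration: float = 0.0
    max_concentration: float | None = None

    def __post_init__(self):
        if self.direction not in ("gradient", "anti-gradient"):
            raise ValueError(f"unknown direction {self.direction!r}")


def pick_gradient_coordinate(
    state,
    from_c: Coord,
    rule: GradientRule,
    *,
    ignore_occupancy: bool = False,
    exclude: tuple[Coord, ...] = (),
) -> Coord | None:
    """Randomly pick a satisfactory neighbor coordinate, or None.

    Candidates are the (vacant, unless ``ignore_occupancy``) radius-1
    neighbors that satisfy the rule's concentration band.  Among those,
    strict improvers along the configured direction are preferred; when no
    candidate strictly improves (a plateau) same-concentration candidates
    are kept, so motion on flat fields remains possible.  The returned
    coordinate is drawn uniformly from the kept set.
    """
    lattice: Lattice = state.lattice
    field: FactorField = state.fields[rule.factor]
    cands = [
        c
        for c in neighborhood(from_c, 1, lattice)
        if (ignore_occupancy or lattice.is_vacant(c)) and c not in exclude
    ]
    if rule.min_concentration > 0 or rule.max_concentration is not None:
        hi = math.inf if rule.max_concentration is None else rule.max_concentration
        cands = [
            c
            for c in cands
            if rule.min_concentration <= field.concentration_at(c) <= hi
        ]
    if not cands:
        return None
    c0 = field.concentration_at(from_c)
    if rule.direction == "gradient":
        strict = [c for c in cands if field.concentration_at(c) > c0]
    else:
        strict = [c for c in cands if field.concentration_at(c) < c0]
    kept = strict or [c for c in cands if field.concentration_at(c) == c0]
    if not kept:
        return None
    return kept[int(state.rng.integers(len(kept)))]
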