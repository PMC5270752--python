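"""Carotenoid-type resolution from (ν1, ν2, ν3) band-position triplets.

At ~1 cm⁻¹ spectral resolution, shifts in the resonance band positions
fingerprint the carotenoid structure (conjugation length, end groups).  Two
cells carry the same carotenoid type when their triplets agree within a
tolerance on every band — i.e. within Chebyshev distance
d(a, b) = max(|Δν1|, |Δν2|, |Δν3|).  Types are formed by single-linkage
grouping: cells share a type iff connected by a chain of pairs with d ≤ tol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

#: Default tolerance: 2 cm⁻¹, twice the stated spectral resolution, absorbing
#: peak-position jitter from noise.
DEFAULT_TOL_CM1 = 2.0


@dataclass(frozen=True)
class CarotenoidTriplet:
    """One cell's matched (ν1, ν2, ν3) positions in cm⁻¹."""

    cell_id: str
    v1: float
    v2: float
    v3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.v1, self.v2, self.v3])


@dataclass
class TypeAssignment:
    """Partition of carotenoid cells into types.

    Type indices are 0-based and ordered by ascending centroid ν3, then ν2,
    then ν1, so the labelling is a pure function of the partition.
    """

    assignments: dict[str, int]           # cell_id -> type index
    n_types: int
    centroids: list[tuple[float, float, float]]  # mean triplet per type

    def members(self, type_index: int) -> list[str]:
        return sorted(c for c, t in self.assignments.items() if t == type_index)


def cluster_types(triplets: list[CarotenoidTriplet],
                  tol_cm1: float = DEFAULT_TOL_CM1,
                  method: str = "single") -> TypeAssignment:
    """Group triplets into carotenoid types under Chebyshev tolerance.

    ``method`` is ``"single"`` (default; chain-connected grouping, exactly
    the connected components of the d ≤ tol graph) or ``"complete"``
    (every within-type pair must satisfy d ≤ tol; no chaining).
    """
    if tol_cm1 < 0:
        raise ValueError("tol_cm1 must be >= 0")
    if method not in ("single", "complete"):
        raise ValueError(f"unknown linkage method {method!r}")
    n = len(triplets)
    if n == 0:
        return TypeAssignment(assignments={}, n_types=0, centroids=[])
    if n == 1:
        t = triplets[0]
        return TypeAssignment(assignments={t.cell_id: 0}, n_types=1,
                              centroids=[(t.v1, t.v2, t.v3)])

    pts = np.vstack([t.as_array() for t in triplets])
    dist = pdist(pts, metric="chebyshev")
    tree = linkage(dist, method=method)
    raw = fcluster(tree, t=tol_cm1, criterion="distance")

    # Deterministic relabelling by centroid order (v3, v2, v1 ascending).
    raw_ids = sorted(set(raw))
    cents = {}
    for rid in raw_ids:
        cents[rid] = pts[raw == rid].mean(axis=0)
    order = sorted(raw_ids, key=lambda r: (cents[r][2], cents[r][1], cents[r][0]))
    remap = {rid: i for i, rid in enumerate(order)}

    assignments = {t.cell_id: remap[r] for t, r in zip(triplets, raw)}
    centroids = [tuple(np.round(cents[rid], 6)) for rid in order]
    return TypeAssignment(assignments=assignments, n_types=len(order),
                          centroids=centroids)


def count_types(assignment: TypeAssignment) -> int:
    """Number of distinct carotenoid types in an assignment."""
    return assignment.n_types


def triplets_from_calls(calls) -> list[CarotenoidTriplet]:
    """Extract triplets from carotenoid-labelled phenotype calls."""
    out = []
    for c in calls:
        if c.label == "carotenoid" and c.triplet is not None:
            out.append(CarotenoidTriplet(c.cell_id, *c.triplet))
    return out
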