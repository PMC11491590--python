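"""Spatial neighbourhood structure and the Leroux CAR precision matrix.

The spatial prior used throughout this package is the Leroux conditional
autoregressive (CAR) prior: for a vector of area-level random effects
``S`` over ``n`` areas with binary adjacency matrix ``W`` and degree
matrix ``D``, the prior is ``S ~ N(0, Q^{-1})`` with precision

    Q = (1/sigma2) * [rho * (D - W) + (1 - rho) * I]

where ``rho`` in [0, 1) blends an intrinsic autoregressive structure
(rho -> 1) with independence (rho = 0) and ``sigma2 > 0`` scales the
marginal variability.  For ``rho < 1`` the matrix is strictly diagonally
dominant, hence positive definite, and the prior is proper without any
sum-to-zero constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "RegionGraph",
    "ValidationError",
    "build_graph",
    "contiguity_from_polygons",
    "leroux_precision",
    "structure_matrix",
]


class ValidationError(ValueError):
    """Raised when input data violate a structural contract."""


@dataclass(frozen=True)
class RegionGraph:
    """Areas plus symmetric adjacency, the basis of the CAR precision.

    Parameters
    ----------
    area_ids
        Ordered area identifiers; the ordering fixes the row/column
        order of every matrix built from the graph.
    edges
        Unordered pairs of neighbouring area ids (no self-loops).
    """

    area_ids: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {a: i for i, a in enumerate(self.area_ids)}
        )

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, area_id: str) -> int:
        return self._index[area_id]

    def edge_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two integer arrays (i < j), sorted for determinism."""
        pairs = sorted(
            tuple(sorted((self._index[a], self._index[b])))
            for a, b in (tuple(e) for e in self.edges)
        )
        if not pairs:
            return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
        arr = np.asarray(pairs, dtype=np.intp)
        return arr[:, 0], arr[:, 1]

    def adjacency(self) -> sp.csr_matrix:
        """Binary symmetric adjacency matrix W in area order."""
        i, j = self.edge_index_arrays()
        data = np.ones(2 * len(i))
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def degrees(self) -> np.ndarray:
        i, j = self.edge_index_arrays()
        deg = np.zeros(self.n)
        np.add.at(deg, i, 1.0)
        np.add.at(deg, j, 1.0)
        return deg

    def neighbors(self, area_id: str) -> list[str]:
        out = []
        for e in self.edges:
            pair = tuple(e)
            if area_id in pair:
                other = pair[0] if pair[1] == area_id else pair[1]
                out.append(other)
        return sorted(out)


def build_graph(edge_list, area_ids) -> RegionGraph:
    """Build a :class:`RegionGraph` from an edge list.

    Edges are symmetrized and deduplicated; self-loops are dropped.

    Raises
    ------
    ValidationError
        If an edge references an unknown area id or ids are duplicated.
    """
    ids = tuple(str(a) for a in area_ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for a in ids:
            if a in seen:
                dups.append(a)
            seen.add(a)
        raise ValidationError(f"duplicate area ids: {sorted(set(dups))}")
    known = set(ids)
    edges = set()
    for a, b in edge_list:
        a, b = str(a), str(b)
        for x in (a, b):
            if x not in known:
                raise ValidationError(f"edge references unknown area id {x!r}")
        if a == b:
            continue
        edges.add(frozenset((a, b)))
    return RegionGraph(area_ids=ids, edges=frozenset(edges))


def contiguity_from_polygons(features) -> RegionGraph:
    """Queen-contiguity graph from (area_id, shapely geometry) pairs.

    Two areas are neighbours iff their polygons share at least one
    boundary point (queen contiguity).  Accepts a mapping or an iterable
    of ``(id, geometry)`` pairs.
    """
    from shapely import STRtree
    from shapely.geometry.base import BaseGeometry

    if hasattr(features, "items"):
        items = list(features.items())
    else:
        items = list(features)
    ids = []
    geoms = []
    for area_id, geom in items:
        if area_id is None:
            raise ValidationError("feature missing area id")
        if not isinstance(geom, BaseGeometry) or geom.is_empty:
            raise ValidationError(f"invalid geometry for area {area_id!r}")
        if not geom.is_valid:
            raise ValidationError(f"invalid geometry for area {area_id!r}")
        ids.append(str(area_id))
        geoms.append(geom)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate area ids in polygon collection")

    tree = STRtree(geoms)
    edges = []
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            # queen contiguity: any shared point (corner contact included)
            if g.intersects(geoms[j]):
                edges.append((ids[i], ids[j]))
    return build_graph(edges, ids)


def structure_matrix(graph: RegionGraph, rho: float) -> sp.csr_matrix:
    """Unscaled Leroux structure matrix R = rho*(D - W) + (1 - rho)*I."""
    W = graph.adjacency()
    D = sp.diags(graph.degrees())
    eye = sp.identity(graph.n, format="csr")
    return (rho * (D - W) + (1.0 - rho) * eye).tocsr()


def leroux_precision(graph: RegionGraph, rho: float, sigma2: float) -> sp.csr_matrix:
    """Sparse Leroux CAR precision Q = (1/sigma2)[rho(D - W) + (1 - rho)I].

    Raises
    ------
    ValueError
        If ``rho`` is outside [0, 1) or ``sigma2 <= 0``.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if not sigma2 > 0.0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    return (structure_matrix(graph, rho) / sigma2).tocsr()
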