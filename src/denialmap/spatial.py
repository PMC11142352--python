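"""Spatial structure: queen-contiguity adjacency and Global Moran's I.

Census tracts are treated as neighbors when their polygons share at least
one boundary point (edge or corner — "queen" contiguity), giving a binary,
symmetric weight matrix ``w_gj`` with zero diagonal.  Global Moran's I on a
per-tract surface screens each metropolitan area for spatial autocorrelation
before any model is fit; inference is by random relabeling permutations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from shapely import STRtree
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "TractGeometry",
    "AdjacencyStructure",
    "MoranResult",
    "build_adjacency",
    "moran_i",
    "read_edge_list",
    "write_edge_list",
]


@dataclass
class TractGeometry:
    """Tract polygons with their GEOIDs and MSA membership, in fixed order."""

    geoids: list[str]
    msa_ids: list[str]
    polygons: list[BaseGeometry]

    def __post_init__(self) -> None:
        if not (len(self.geoids) == len(self.msa_ids) == len(self.polygons)):
            raise ValueError("geoids, msa_ids and polygons must have equal length")
        if len(set(self.geoids)) != len(self.geoids):
            raise ValueError("duplicate tract GEOIDs in geometry")

    def __len__(self) -> int:
        return len(self.geoids)

    def subset_msa(self, msa_id: str) -> "TractGeometry":
        keep = [i for i, m in enumerate(self.msa_ids) if m == msa_id]
        return TractGeometry(
            geoids=[self.geoids[i] for i in keep],
            msa_ids=[self.msa_ids[i] for i in keep],
            polygons=[self.polygons[i] for i in keep],
        )

    @property
    def msas(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.msa_ids:
            seen.setdefault(m)
        return list(seen)

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"tract_geoid": g, "msa_id": m},
                "geometry": shapely_mapping(p),
            }
            for g, m, p in zip(self.geoids, self.msa_ids, self.polygons)
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )

    @classmethod
    def from_geojson(cls, path: str | Path) -> "TractGeometry":
        fc = json.loads(Path(path).read_text())
        geoids, msa_ids, polys = [], [], []
        for feat in fc["features"]:
            props = feat.get("properties", {})
            geoids.append(str(props["tract_geoid"]))
            msa_ids.append(str(props.get("msa_id", "")))
            polys.append(shapely_shape(feat["geometry"]))
        return cls(geoids, msa_ids, polys)


@dataclass
class AdjacencyStructure:
    """Binary queen-contiguity weights over a fixed tract ordering.

    Attributes
    ----------
    ids : node labels (tract GEOIDs), fixed order matching ``W`` rows.
    W : binary symmetric scipy CSR matrix with zero diagonal.
    degrees : per-node neighbor counts ``sum_j w_gj``.
    S0 : total weight ``sum_g sum_j w_gj`` (twice the edge count).
    component_labels : connected-component index per node.
    """

    ids: list[str]
    W: sparse.csr_matrix
    degrees: np.ndarray = field(init=False)
    S0: float = field(init=False)
    component_labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        W = sparse.csr_matrix(self.W, dtype=float)
        if W.shape[0] != W.shape[1] or W.shape[0] != len(self.ids):
            raise ValueError("weight matrix shape does not match node ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate node ids")
        if W.diagonal().any():
            raise ValueError("weight matrix must have zero diagonal")
        if (W != W.T).nnz:
            raise ValueError("weight matrix must be symmetric")
        self.W = W
        self.degrees = np.asarray(W.sum(axis=1)).ravel()
        self.S0 = float(self.degrees.sum())
        _, labels = connected_components(W, directed=False)
        self.component_labels = labels

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n else 0

    @property
    def neighbors(self) -> dict[str, list[str]]:
        idx = self.W.tolil().rows
        return {self.ids[i]: [self.ids[j] for j in idx[i]] for i in range(self.n)}

    def laplacian(self) -> sparse.csr_matrix:
        return sparse.diags(self.degrees) - self.W

    def edges(self) -> list[tuple[str, str]]:
        coo = sparse.triu(self.W, k=1).tocoo()
        out = [(self.ids[i], self.ids[j]) for i, j in zip(coo.row, coo.col)]
        return sorted(tuple(sorted(e)) for e in out)

    @classmethod
    def from_edges(
        cls, ids: Sequence[str], edges: Iterable[tuple[str, str]]
    ) -> "AdjacencyStructure":
        pos = {g: i for i, g in enumerate(ids)}
        rows, cols = [], []
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            rows += [pos[a], pos[b]]
            cols += [pos[b], pos[a]]
        W = sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(ids), len(ids))
        ).tocsr()
        W.data[:] = 1.0  # collapse duplicate edge listings
        return cls(ids=list(ids), W=W)

    def subset(self, keep_ids: Sequence[str]) -> "AdjacencyStructure":
        pos = {g: i for i, g in enumerate(self.ids)}
        idx = np.array([pos[g] for g in keep_ids], dtype=int)
        return AdjacencyStructure(ids=list(keep_ids), W=self.W[np.ix_(idx, idx)])


def build_adjacency(geometry: TractGeometry | Mapping[str, BaseGeometry]) -> AdjacencyStructure:
    """Queen-contiguity adjacency: ``w_gj = 1`` iff polygons share >= 1 boundary point.

    Accepts a :class:`TractGeometry` or a mapping ``geoid -> polygon``.
    Raises on empty input or duplicate ids.
    """
    if isinstance(geometry, TractGeometry):
        ids, polys = geometry.geoids, geometry.polygons
    else:
        ids, polys = list(geometry.keys()), list(geometry.values())
    if not ids:
        raise ValueError("empty geometry")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate tract GEOIDs")

    tree = STRtree(polys)
    rows: list[int] = []
    cols: list[int] = []
    for i, poly in enumerate(polys):
        # queen contiguity: any shared boundary point, interiors disjoint
        for j in tree.query(poly, predicate="touches"):
            j = int(j)
            if j != i:
                rows.append(i)
                cols.append(j)
    W = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(ids), len(ids))
    ).tocsr()
    W.data[:] = 1.0
    return AdjacencyStructure(ids=list(ids), W=W)


def write_edge_list(adjacency: AdjacencyStructure, path: str | Path) -> None:
    """Plain-text edge list, one ``geoid_a geoid_b`` pair per line, sorted."""
    lines = [f"{a} {b}" for a, b in adjacency.edges()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_edge_list(path: str | Path, ids: Sequence[str] | None = None) -> AdjacencyStructure:
    """Read an edge list written by :func:`write_edge_list`.

    ``ids`` fixes the node order (and admits isolated nodes); when omitted the
    order is the sorted set of endpoint labels.
    """
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split()
        edges.append((a, b))
    if ids is None:
        ids = sorted({g for e in edges for g in e})
    return AdjacencyStructure.from_edges(ids, edges)


@dataclass
class MoranResult:
    """Global Moran's I with its permutation-based two-sided p-value."""

    I: float
    expected: float  # analytic null expectation -1/(n-1)
    p_value: float
    n_permutations: int
    n: int
    significant: bool
    alpha: float
    seed: int | None = None


def moran_i(
    values: np.ndarray,
    adjacency: AdjacencyStructure,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = 0,
    row_standardize: bool = False,
) -> MoranResult:
    """Global Moran's I with permutation inference.

    I = (n / S0) * sum_gj w_gj (x_g - xbar)(x_j - xbar) / sum_g (x_g - xbar)^2

    Weights are binary by default (matching w_gj in {0, 1}); set
    ``row_standardize`` for the common W-standardized variant.  The p-value is
    two-sided around the permutation mean of I.  Isolated (degree-0) nodes are
    dropped with a warning, since they contribute nothing to the numerator.
    """
    x = np.asarray(values, dtype=float)
    if x.shape != (adjacency.n,):
        raise ValueError("values must align with adjacency node order")
    W = adjacency.W
    if (adjacency.degrees == 0).any():
        keep = np.flatnonzero(adjacency.degrees > 0)
        warnings.warn(
            f"dropping {adjacency.n - keep.size} isolated node(s) from Moran's I",
            stacklevel=2,
        )
        x = x[keep]
        W = W[np.ix_(keep, keep)]
    n = x.size
    if n < 3:
        raise ValueError("Moran's I requires at least 3 connected nodes")
    if np.ptp(x) == 0:
        raise ValueError("constant surface: Moran's I undefined (zero variance)")
    if row_standardize:
        W = sparse.diags(1.0 / np.asarray(W.sum(axis=1)).ravel()) @ W
    S0 = float(W.sum())

    def stat(v: np.ndarray) -> float:
        z = v - v.mean()
        return float(n / S0 * (z @ (W @ z)) / (z @ z))

    I_obs = stat(x)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for k in range(n_permutations):
        perms[k] = stat(rng.permutation(x))
    center = perms.mean()
    extreme = np.abs(perms - center) >= abs(I_obs - center) - 1e-15
    p = (1.0 + int(extreme.sum())) / (n_permutations + 1.0)
    return MoranResult(
        I=I_obs,
        expected=-1.0 / (n - 1),
        p_value=p,
        n_permutations=n_permutations,
        n=n,
        significant=p <= alpha,
        alpha=alpha,
        seed=seed,
    )
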