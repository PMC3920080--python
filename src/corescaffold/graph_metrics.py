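"""Global and nodal network measures used throughout the lesion analysis.

Conventions
-----------
* Weight-to-length rule: an edge of weight ``w > 0`` has length ``1/w``
  (strong connections are short). The rule is configurable per call.
* Shortest paths: Dijkstra over the length matrix
  (``scipy.sparse.csgraph``); disconnected pairs have distance ``+inf``.
* Characteristic path length uses the finite-pairs convention: the mean is
  taken over connected (finite) off-diagonal pairs only, so that lesioned,
  possibly disconnected networks still yield a finite value; the number of
  disconnected pairs is reported separately.
* Transitivity, clustering, degree and assortativity are computed on the
  binary topology (edge present iff weight > 0).
* Mathematically undefined values (assortativity on a regular graph,
  transitivity with no connected triple, path length of an edgeless graph)
  raise :class:`UndefinedMetricError` rather than returning NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from corescaffold.exceptions import UndefinedMetricError
from corescaffold.parcellation_io import Connectome

#: Order of the global feature vector used by the edge-removal tests.
FEATURE_NAMES = ("assortativity", "lambda", "density", "transitivity")

ArrayLike = Union[Connectome, np.ndarray]


def _weights(x: ArrayLike) -> np.ndarray:
    return x.weights if isinstance(x, Connectome) else np.asarray(x, dtype=float)


def inverse_weight(weights: np.ndarray) -> np.ndarray:
    """Default weight-to-length rule: length = 1/weight on present edges."""
    lengths = np.zeros_like(weights)
    nz = weights > 0
    lengths[nz] = 1.0 / weights[nz]
    return lengths


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path lengths (``+inf`` where no path exists)."""

    d: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.d.shape[0]

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, 1)
        return self.d[iu]

    def n_disconnected_pairs(self) -> int:
        """Unordered node pairs with no connecting path."""
        return int(np.sum(~np.isfinite(self.offdiag())))


def distance_matrix(connectome: ArrayLike,
                    rule: Callable[[np.ndarray], np.ndarray] = inverse_weight,
                    ) -> DistanceMatrix:
    """Shortest-path distance matrix under the given weight-to-length rule."""
    lengths = rule(_weights(connectome))
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    return DistanceMatrix(d=d)


def characteristic_path_length(dm: DistanceMatrix) -> float:
    """Mean shortest-path distance over connected off-diagonal pairs.

    The integration measure (lambda): the global average of the
    distance-matrix entries. Disconnected pairs are excluded from the mean
    (finite-pairs convention); use :meth:`DistanceMatrix.n_disconnected_pairs`
    to see how many were excluded. Raises if no pair is connected.
    """
    off = dm.offdiag()
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        raise UndefinedMetricError("lambda", "graph has no connected node pair")
    return float(finite.mean())


def local_efficiency(connectome: ArrayLike,
                     rule: Callable[[np.ndarray], np.ndarray] = inverse_weight,
                     ) -> np.ndarray:
    """Per-node local efficiency (neighbor-subgraph inverse distances).

    For each node, the subgraph induced by its neighbors is extracted,
    shortest-path distances are computed within it under the same
    weight-to-length rule, and the inverse distances (0 for disconnected
    pairs) are averaged over ordered neighbor pairs. Nodes with fewer than
    two neighbors have local efficiency 0. The network's segregation measure
    is the mean of this vector.
    """
    W = _weights(connectome)
    n = W.shape[0]
    eff = np.zeros(n)
    adj = W > 0
    for u in range(n):
        nb = np.flatnonzero(adj[u])
        k = nb.size
        if k < 2:
            continue
        sub = W[np.ix_(nb, nb)]
        d = shortest_path(csr_matrix(inverse_weight_like(rule, sub)),
                          method="D", directed=False)
        inv = np.zeros_like(d)
        finite = np.isfinite(d) & ~np.eye(k, dtype=bool)
        inv[finite] = 1.0 / d[finite]
        eff[u] = inv.sum() / (k * (k - 1))
    return eff


def inverse_weight_like(rule, sub: np.ndarray) -> np.ndarray:
    return rule(sub)


def degree(connectome: ArrayLike) -> np.ndarray:
    """Binary degree: number of edges incident to each node."""
    return (_weights(connectome) > 0).sum(axis=0)


def density(connectome: ArrayLike) -> float:
    """Fraction of possible edges present (binary topology)."""
    W = _weights(connectome)
    n = W.shape[0]
    if n < 2:
        raise UndefinedMetricError("density", "graph has fewer than 2 nodes")
    iu = np.triu_indices(n, 1)
    return float((W[iu] > 0).mean())


def assortativity(connectome: ArrayLike) -> float:
    """Degree-degree Pearson correlation over the symmetrized edge list.

    Newman's assortativity on the binary topology. Undefined (and raised as
    such) when the graph has fewer than 2 edges or all endpoint degrees are
    equal (zero variance, e.g. a cycle).
    """
    W = _weights(connectome)
    A = W > 0
    i, j = np.nonzero(np.triu(A, 1))
    if i.size < 2:
        raise UndefinedMetricError("assortativity", "graph has fewer than 2 edges")
    k = A.sum(axis=0)
    # symmetrized endpoint lists: each edge contributes (ki,kj) and (kj,ki)
    x = np.concatenate([k[i], k[j]]).astype(float)
    y = np.concatenate([k[j], k[i]]).astype(float)
    vx = x.var()
    if vx == 0:
        raise UndefinedMetricError(
            "assortativity", "all endpoint degrees equal (zero variance)")
    return float(((x - x.mean()) * (y - y.mean())).mean() / vx)


def transitivity(connectome: ArrayLike) -> float:
    """3 x triangles / connected triples, on the binary topology."""
    A = (_weights(connectome) > 0).astype(float)
    k = A.sum(axis=0)
    triples = float((k * (k - 1)).sum())
    if triples == 0:
        raise UndefinedMetricError("transitivity", "graph has no connected triple")
    triangles3 = float(np.trace(A @ A @ A))  # = 6 * triangles
    return triangles3 / triples


def clustering(connectome: ArrayLike) -> np.ndarray:
    """Per-node clustering coefficient (binary triangle fraction)."""
    A = (_weights(connectome) > 0).astype(float)
    k = A.sum(axis=0)
    tri = np.diag(A @ A @ A)  # 2 * triangles through each node
    denom = k * (k - 1)
    out = np.zeros_like(tri)
    nz = denom > 0
    out[nz] = tri[nz] / denom[nz]
    return out


def eccentricity(dm: DistanceMatrix) -> np.ndarray:
    """Per-node greatest finite distance (0 for isolated nodes)."""
    d = dm.d.copy()
    np.fill_diagonal(d, np.nan)
    with np.errstate(invalid="ignore"):
        finite = np.where(np.isfinite(d), d, np.nan)
    ecc = np.nanmax(np.where(np.isnan(finite), -np.inf, finite), axis=1)
    ecc[ecc == -np.inf] = 0.0
    return ecc


def radius(dm: DistanceMatrix) -> float:
    """Minimum eccentricity over nodes."""
    ecc = eccentricity(dm)
    return float(ecc.min())


def diameter(dm: DistanceMatrix) -> float:
    """Largest finite entry of the distance matrix.

    For a disconnected graph this is the largest finite distance; pair it
    with :meth:`DistanceMatrix.n_disconnected_pairs` when reporting.
    """
    off = dm.offdiag()
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        raise UndefinedMetricError("diameter", "graph has no connected node pair")
    return float(finite.max())


def betweenness(connectome: ArrayLike,
                rule: Callable[[np.ndarray], np.ndarray] = inverse_weight,
                ) -> np.ndarray:
    """Unnormalized shortest-path betweenness on inverse-weight lengths.

    Counts, for each node v, the sum over unordered pairs (s, t) of the
    fraction of shortest s-t paths passing through v.
    """
    import networkx as nx

    W = _weights(connectome)
    lengths = rule(W)
    g = nx.from_numpy_array(lengths)
    # from_numpy_array stores the length as 'weight'
    bc = nx.betweenness_centrality(g, weight="weight", normalized=False)
    return np.array([bc[i] for i in range(W.shape[0])])


@dataclass(frozen=True)
class GlobalMetrics:
    """Bundle of global measures for one network, for reporting."""

    lambda_: float
    local_efficiency_avg: float
    assortativity: float
    density: float
    transitivity: float
    diameter: float
    radius: float
    n_disconnected_pairs: int


def global_metrics(connectome: ArrayLike) -> GlobalMetrics:
    dm = distance_matrix(connectome)
    return GlobalMetrics(
        lambda_=characteristic_path_length(dm),
        local_efficiency_avg=float(local_efficiency(connectome).mean()),
        assortativity=assortativity(connectome),
        density=density(connectome),
        transitivity=transitivity(connectome),
        diameter=diameter(dm),
        radius=radius(dm),
        n_disconnected_pairs=dm.n_disconnected_pairs(),
    )


@dataclass(frozen=True)
class FeatureVector:
    """The p=4 global feature vector for edge-removal tests.

    ``values`` holds (assortativity, lambda, density, transitivity) in that
    order, with NaN at positions whose metric is undefined on this graph;
    ``undefined`` names those metrics.
    """

    values: np.ndarray
    undefined: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError("feature vector must have length 4")


def feature_vector(connectome: ArrayLike,
                   dm: DistanceMatrix | None = None) -> FeatureVector:
    """(assortativity, lambda, density, transitivity) with undefined flags."""
    values = np.empty(len(FEATURE_NAMES))
    undefined: list[str] = []
    if dm is None:
        dm = distance_matrix(connectome)
    calls = {
        "assortativity": lambda: assortativity(connectome),
        "lambda": lambda: characteristic_path_length(dm),
        "density": lambda: density(connectome),
        "transitivity": lambda: transitivity(connectome),
    }
    for idx, name in enumerate(FEATURE_NAMES):
        try:
            values[idx] = calls[name]()
        except UndefinedMetricError:
            values[idx] = np.nan
            undefined.append(name)
    return FeatureVector(values=values, undefined=tuple(undefined))
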