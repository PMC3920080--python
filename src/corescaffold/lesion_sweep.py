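"""Single-node and single-edge lesion sweeps over a cohort.

A node lesion deletes one cortical parcel and all its connections and
recomputes the two global measures (characteristic path length, mean local
efficiency) on the (G-1)-node network; weights are not renormalized after
lesioning. An edge lesion zeroes one connection and recomputes the p=4
global feature vector. Sweeps cover, per subject, all lesionable cortical
parcels (148 under the default scheme) and all G(G-1)/2 unordered node
pairs respectively; lesioning an edge absent in a subject reproduces that
subject's intact vector exactly (shortcut, no recomputation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from corescaffold.exceptions import UndefinedMetricError
from corescaffold.parcellation_io import Cohort, Connectome
from corescaffold.graph_metrics import (
    FEATURE_NAMES,
    FeatureVector,
    characteristic_path_length,
    distance_matrix,
    feature_vector,
    local_efficiency,
)

NODE_METRICS = ("lambda", "local_efficiency_avg")


def remove_node(connectome: Connectome, parcel: int) -> Connectome:
    """Delete one node and its incident edges; remaining weights untouched.

    Returns an (n-1)-node connectome whose ``node_ids`` records the original
    parcel index of every surviving row.
    """
    n = connectome.n_nodes
    ids = connectome.original_ids()
    pos = np.flatnonzero(ids == parcel)
    if pos.size == 0:
        raise ValueError(f"parcel {parcel} not present in this network")
    keep = np.arange(n) != pos[0]
    sub = connectome.weights[np.ix_(keep, keep)]
    return Connectome(
        subject_id=connectome.subject_id,
        weights=sub,
        parcellation=connectome.parcellation,
        node_ids=ids[keep],
    )


def remove_edge(connectome: Connectome, i: int, j: int) -> Connectome:
    """Zero the (i, j) connection; removing an absent edge is the identity."""
    if i == j:
        raise ValueError("an edge requires two distinct nodes")
    if connectome.weights[i, j] == 0:
        return connectome
    W = connectome.weights.copy()
    W[i, j] = W[j, i] = 0.0
    lengths = fa = None
    if connectome.lengths is not None:
        lengths = connectome.lengths.copy()
        lengths[i, j] = lengths[j, i] = 0.0
    if connectome.fa is not None:
        fa = connectome.fa.copy()
        fa[i, j] = fa[j, i] = 0.0
    return replace(connectome, weights=W, lengths=lengths, fa=fa)


def _node_metrics(connectome: Connectome) -> tuple[dict[str, float], int]:
    """(metric values with NaN where undefined, n disconnected pairs)."""
    dm = distance_matrix(connectome)
    try:
        lam = characteristic_path_length(dm)
    except UndefinedMetricError:
        lam = np.nan
    eff = float(local_efficiency(connectome).mean())
    return ({"lambda": lam, "local_efficiency_avg": eff},
            dm.n_disconnected_pairs())


@dataclass(frozen=True)
class NodeLesionTable:
    """Node-lesion metric values: arrays indexed (lesion, subject).

    ``lesioned[m]`` has shape (n_lesions, N); ``intact[m]`` has shape (N,).
    NaN marks undefined (flagged) cells; ``n_missing`` counts them.
    """

    parcels: np.ndarray           # lesioned parcel ids, shape (n_lesions,)
    subjects: tuple[str, ...]
    lesioned: dict[str, np.ndarray]
    intact: dict[str, np.ndarray]
    n_missing: int

    @property
    def n_lesions(self) -> int:
        return self.parcels.size

    @property
    def N(self) -> int:
        return len(self.subjects)

    def lesion_means(self, metric: str) -> np.ndarray:
        """Per-lesion mean over subjects (the cohort-average lesioned value)."""
        return np.nanmean(self.lesioned[metric], axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (lesion, subject, metric, value) table."""
        rows = []
        for m in NODE_METRICS:
            for li, parcel in enumerate(self.parcels):
                for si, sid in enumerate(self.subjects):
                    rows.append((int(parcel), sid, m, self.lesioned[m][li, si]))
            for si, sid in enumerate(self.subjects):
                rows.append((-1, sid, m, self.intact[m][si]))
        return pd.DataFrame(rows, columns=["lesion", "subject", "metric", "value"])


def node_lesion_sweep(cohort: Cohort,
                      parcels: Optional[Sequence[int]] = None,
                      ) -> NodeLesionTable:
    """Lesion every cortical parcel in every subject and recompute metrics.

    ``parcels`` overrides the default lesion set (all cortical parcels of the
    cohort's parcellation; 148 under the default 165-parcel scheme).
    """
    if parcels is None:
        parcels = cohort.parcellation.cortical_ids()
    parcels = np.asarray(parcels, dtype=int)
    N = cohort.N
    lesioned = {m: np.empty((parcels.size, N)) for m in NODE_METRICS}
    intact = {m: np.empty(N) for m in NODE_METRICS}
    n_missing = 0
    for si, subject in enumerate(cohort):
        vals, _ = _node_metrics(subject)
        for m in NODE_METRICS:
            intact[m][si] = vals[m]
        for li, parcel in enumerate(parcels):
            vals, _ = _node_metrics(remove_node(subject, int(parcel)))
            for m in NODE_METRICS:
                lesioned[m][li, si] = vals[m]
                if np.isnan(vals[m]):
                    n_missing += 1
    return NodeLesionTable(parcels=parcels,
                           subjects=tuple(c.subject_id for c in cohort),
                           lesioned=lesioned, intact=intact,
                           n_missing=n_missing)


@dataclass(frozen=True)
class EdgeLesionTable:
    """Edge-lesion feature vectors: ``lesioned`` has shape (n_pairs, N, 4).

    ``pairs`` lists all G(G-1)/2 unordered node pairs; ``edge_presence``
    counts, per pair, the subjects in which the edge exists. NaN marks
    feature components that were undefined on the lesioned network.
    """

    pairs: np.ndarray             # shape (n_pairs, 2)
    subjects: tuple[str, ...]
    lesioned: np.ndarray          # (n_pairs, N, p)
    intact: np.ndarray            # (N, p)
    edge_presence: np.ndarray     # (n_pairs,)
    feature_names: tuple[str, ...] = FEATURE_NAMES
    n_missing: int = 0

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    @property
    def N(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pi, (i, j) in enumerate(self.pairs):
            for si, sid in enumerate(self.subjects):
                for mi, m in enumerate(self.feature_names):
                    rows.append((int(i), int(j), sid, m,
                                 self.lesioned[pi, si, mi]))
        return pd.DataFrame(
            rows, columns=["parcel_a", "parcel_b", "subject", "metric", "value"])


def all_pairs(G: int) -> np.ndarray:
    iu = np.triu_indices(G, 1)
    return np.column_stack(iu)


def edge_lesion_sweep(cohort: Cohort) -> EdgeLesionTable:
    """Remove every possible connection in every subject; evaluate features.

    For pairs absent in a subject the intact vector is copied without
    recomputation (removal of an absent edge is the identity).
    """
    G = cohort.G
    pairs = all_pairs(G)
    N = cohort.N
    p = len(FEATURE_NAMES)
    lesioned = np.empty((pairs.shape[0], N, p))
    intact = np.empty((N, p))
    presence = np.zeros(pairs.shape[0], dtype=int)
    n_missing = 0
    for si, subject in enumerate(cohort):
        fv = feature_vector(subject)
        intact[si] = fv.values
        for pi, (i, j) in enumerate(pairs):
            if subject.weights[i, j] == 0:
                lesioned[pi, si] = fv.values
                continue
            presence[pi] += 1
            lv = feature_vector(remove_edge(subject, int(i), int(j)))
            lesioned[pi, si] = lv.values
            n_missing += len(lv.undefined)
    return EdgeLesionTable(pairs=pairs,
                           subjects=tuple(c.subject_id for c in cohort),
                           lesioned=lesioned, intact=intact,
                           edge_presence=presence, n_missing=n_missing)
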