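"""Spatial patterns of lesion effects: correlation matrix, PCA and MPCA.

Node removals: the across-subject correlation matrix R (entry r(k, k') is
the Pearson correlation, across subjects, between the post-lesion value of a
global measure after removing parcel k and after removing parcel k') is
eigendecomposed to find groups of parcels whose removal perturbs the network
similarly. The same machinery applied to per-node metrics of the *intact*
networks gives the comparison baseline: if the leading lesion-PCA loadings
correlated strongly with intact-metric PCA loadings, the lesion analysis
would be redundant.

Edge removals: a rank-3 tensor C[k, k', k''] summarizes, for each removed
connection {k, k'}, its effect on node k'' (collapsed across subjects by
correlating the per-subject nodal effect with the per-subject global path
length effect). Multilinear PCA (alternating partial projections) extracts
per-mode orthonormal projections capturing most of the tensor's variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from corescaffold.exceptions import UndefinedMetricError
from corescaffold.parcellation_io import Cohort
from corescaffold.lesion_sweep import NodeLesionTable, remove_edge, all_pairs
from corescaffold.graph_metrics import (betweenness, clustering,
                                        characteristic_path_length,
                                        distance_matrix, eccentricity,
                                        local_efficiency)


# ---------------------------------------------------------------------------
# correlation matrix of node-lesion effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlations of lesion effects across subjects.

    Rows/columns follow the parcellation's matrix ordering restricted to the
    lesioned parcels (right hemisphere first, antero-posterior within lobe).
    NaN marks entries whose underlying series had zero variance.
    """

    R: np.ndarray
    parcels: np.ndarray
    metric: str
    n_missing: int = 0


def _pearson_matrix(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Row-by-row correlation of X (variables in rows, subjects in columns).

    Rows whose variation is at rounding level relative to their magnitude are
    treated as constant (their correlations are flagged missing) rather than
    correlating numerical noise.
    """
    sd = X.std(axis=1, ddof=1)
    scale = np.abs(X).max(axis=1)
    ok = sd > 1e-12 * np.maximum(scale, np.finfo(float).tiny)
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc @ Xc.T) / np.outer(denom, denom)
    R[~ok, :] = np.nan
    R[:, ~ok] = np.nan
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    n_missing = int(np.isnan(R).sum())
    return R, n_missing


def lesion_correlation_matrix(table: NodeLesionTable, metric: str = "lambda",
                              ) -> CorrelationMatrix:
    """R[i, j]: correlation across subjects of post-lesion metric values."""
    if table.N < 3:
        raise ValueError("need at least 3 subjects to correlate across")
    X = table.lesioned[metric]          # (n_lesions, N), post-lesion values
    if np.isnan(X).any():
        warnings.warn("NaN lesioned values present; correlations use all "
                      "subjects where defined")
    R, n_missing = _pearson_matrix(X)
    return CorrelationMatrix(R=R, parcels=table.parcels, metric=metric,
                             n_missing=n_missing)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    """Loadings (orthonormal columns) and per-component variance fractions."""

    loadings: np.ndarray           # (n_variables, n_components)
    variance_fraction: np.ndarray  # (n_components,)
    metric: str = ""

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic orientation: largest-magnitude entry positive."""
    out = loadings.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, c] = -col
    return out


def pca(matrix: np.ndarray, n_components: int = 3, metric: str = "",
        ) -> PCAResult:
    """PCA via eigendecomposition of the covariance of the columns.

    ``matrix`` is observations x variables (for the symmetric correlation
    matrix R, rows play the role of observations). NaN entries (flagged
    missing correlations) are imputed to 0 for the decomposition. Requesting
    more components than the covariance rank truncates with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    X = np.where(np.isnan(X), 0.0, X)
    C = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total == 0:
        raise UndefinedMetricError("pca", "zero total variance")
    rank = int(np.sum(evals > 1e-12 * evals[0]))
    if n_components > rank:
        warnings.warn(f"requested {n_components} components but covariance "
                      f"rank is {rank}; truncating")
        n_components = rank
    return PCAResult(loadings=_fix_signs(evecs[:, :n_components]),
                     variance_fraction=evals[:n_components] / total,
                     metric=metric)


_NODAL_METRICS = {
    "betweenness": lambda c: betweenness(c),
    "clustering": lambda c: clustering(c),
    "eccentricity": lambda c: eccentricity(distance_matrix(c)),
    "local_efficiency": lambda c: local_efficiency(c),
}


def intact_metric_pca(cohort: Cohort, metric: str, n_components: int = 3,
                      parcels: Optional[Sequence[int]] = None) -> PCAResult:
    """PCA of the across-subject correlation matrix of an intact nodal metric.

    ``metric`` is one of betweenness / clustering / eccentricity (or
    local_efficiency); values are taken on each subject's intact network at
    the cortical parcels (or ``parcels``), correlated across subjects node
    against node, and the resulting matrix is decomposed exactly as the
    lesion-effect matrix is.
    """
    if metric not in _NODAL_METRICS:
        raise ValueError(f"unknown nodal metric {metric!r}; choose from "
                         f"{sorted(_NODAL_METRICS)}")
    if parcels is None:
        parcels = cohort.parcellation.cortical_ids()
    parcels = np.asarray(parcels, dtype=int)
    X = np.empty((parcels.size, cohort.N))
    for si, subject in enumerate(cohort):
        X[:, si] = _NODAL_METRICS[metric](subject)[parcels]
    R, n_missing = _pearson_matrix(X)
    offdiag = ~np.eye(R.shape[0], dtype=bool)
    if np.isnan(R[offdiag]).all():
        raise UndefinedMetricError(
            "intact_metric_pca", f"{metric} has zero variance across subjects")
    return pca(R, n_components=n_components, metric=metric)


def compare_lesion_vs_intact(lesion_pca: PCAResult,
                             intact_pcas: dict[str, PCAResult],
                             ) -> "pd.DataFrame":
    """Correlations between lesion-PCA and intact-metric-PCA loadings.

    Returns a tidy table (metric, lesion_component, intact_component, r);
    the maximum |r| is the headline comparison: values below ~0.3 indicate
    the lesion analysis is not reproducible from intact-network metrics.
    """
    import pandas as pd

    rows = []
    for metric, res in intact_pcas.items():
        if res.loadings.shape[0] != lesion_pca.loadings.shape[0]:
            raise ValueError("loading vectors defined on different parcel sets")
        for a in range(lesion_pca.n_components):
            for b in range(res.n_components):
                x = lesion_pca.loadings[:, a]
                y = res.loadings[:, b]
                r = float(np.corrcoef(x, y)[0, 1])
                rows.append((metric, a + 1, b + 1, r))
    return pd.DataFrame(rows, columns=["metric", "lesion_component",
                                       "intact_component", "r"])


# ---------------------------------------------------------------------------
# edge-effect tensor and MPCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeEffectTensor:
    """C[k, k', k'']: across-subject collapse of the effect on node k'' of
    removing edge {k, k'}; symmetric in (k, k'). NaN marks entries whose
    underlying series were degenerate (edge absent everywhere, zero
    variance); ``n_missing`` counts them over the upper triangle.
    """

    C: np.ndarray
    nodal_metric: str
    n_missing: int = 0


def edge_effect_tensor(cohort: Cohort, nodal_metric: str = "eccentricity",
                       ) -> EdgeEffectTensor:
    """Build the rank-3 edge-effect tensor.

    For every unordered pair {k, k'}, the per-subject effect of the removal
    on each node k'' (change of the nodal metric) and on the global path
    length are computed; C[k, k', k''] is the Pearson correlation across
    subjects between the nodal effect at k'' and the global effect. Pairs
    with no effect in any subject, and nodes with zero effect variance,
    yield NaN entries (imputed downstream).
    """
    if nodal_metric not in _NODAL_METRICS:
        raise ValueError(f"unknown nodal metric {nodal_metric!r}")
    fn = _NODAL_METRICS[nodal_metric]
    G = cohort.G
    N = cohort.N
    intact_nodal = np.empty((N, G))
    intact_lambda = np.empty(N)
    for si, subject in enumerate(cohort):
        dm = distance_matrix(subject)
        intact_nodal[si] = fn(subject)
        intact_lambda[si] = characteristic_path_length(dm)
    C = np.full((G, G, G), np.nan)
    n_missing = 0
    for (k, kp) in all_pairs(G):
        d_nodal = np.zeros((N, G))
        d_lambda = np.zeros(N)
        any_effect = False
        for si, subject in enumerate(cohort):
            if subject.weights[k, kp] == 0:
                continue
            lesioned = remove_edge(subject, int(k), int(kp))
            dm = distance_matrix(lesioned)
            d_nodal[si] = fn(lesioned) - intact_nodal[si]
            try:
                d_lambda[si] = (characteristic_path_length(dm)
                                - intact_lambda[si])
            except UndefinedMetricError:
                d_lambda[si] = np.nan
            any_effect = True
        if not any_effect:
            n_missing += G
            continue
        row = _corr_vs_global(d_nodal, d_lambda)
        n_missing += int(np.isnan(row).sum())
        C[k, kp, :] = row
        C[kp, k, :] = row
    return EdgeEffectTensor(C=C, nodal_metric=nodal_metric,
                            n_missing=n_missing)


def _corr_vs_global(d_nodal: np.ndarray, d_lambda: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(d_lambda)
    y = d_lambda[ok]
    X = d_nodal[ok]
    if y.size < 3 or y.std(ddof=1) == 0:
        return np.full(X.shape[1], np.nan)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc ** 2).sum(axis=0)) * np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / denom
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


@dataclass(frozen=True)
class MPCAResult:
    """Per-mode orthonormal projections and the captured variation fraction.

    ``mode_projections`` holds (U1, U2) for the two edge modes; the samples
    are the mode-3 slices (one effect matrix per target region).
    ``mpc1_loadings`` is the first column of the mode-1 (region) projection,
    mappable over the cortex.
    """

    mode_projections: tuple[np.ndarray, np.ndarray]
    captured_variation: float
    mpc1_loadings: np.ndarray
    n_iter: int
    converged: bool
    n_imputed: int = 0


def mpca(tensor: EdgeEffectTensor | np.ndarray,
         n_components_per_mode: tuple[int, int] = (1, 1),
         tol: float = 1e-8, max_iter: int = 200) -> MPCAResult:
    """Multilinear PCA of a rank-3 tensor by alternating partial projections.

    The mode-3 slices are the samples: G matrices of size G x G, centered by
    their mean. Projections are initialized from the full-projection
    truncation (eigenvectors of the per-mode total scatter matrices) and
    refined by alternating eigendecompositions of the partially projected
    scatter until the captured variation changes by less than ``tol`` or
    ``max_iter`` is reached (non-convergence is flagged, not raised).
    Captured variation = projected variation / total variation, and can only
    grow as components are added. Missing (NaN) entries are imputed to 0 and
    counted.
    """
    C = tensor.C if isinstance(tensor, EdgeEffectTensor) else np.asarray(
        tensor, dtype=float)
    if C.ndim != 3:
        raise ValueError("tensor must be rank 3")
    n_imputed = int(np.isnan(C).sum())
    C = np.where(np.isnan(C), 0.0, C)
    d1, d2 = n_components_per_mode
    samples = [C[:, :, k] for k in range(C.shape[2])]
    mean = sum(samples) / len(samples)
    A = [s - mean for s in samples]
    total = sum(float((a ** 2).sum()) for a in A)
    if total == 0:
        U1 = np.eye(C.shape[0])[:, :d1]
        U2 = np.eye(C.shape[1])[:, :d2]
        return MPCAResult((U1, U2), 1.0, U1[:, 0], 0, True, n_imputed)

    def top_eigvecs(S: np.ndarray, d: int) -> np.ndarray:
        evals, evecs = np.linalg.eigh(S)
        return evecs[:, np.argsort(evals)[::-1][:d]]

    # full-projection (HOSVD-style) initialization
    U1 = top_eigvecs(sum(a @ a.T for a in A), d1)
    U2 = top_eigvecs(sum(a.T @ a for a in A), d2)

    def captured(U1, U2) -> float:
        return sum(float(((U1.T @ a @ U2) ** 2).sum()) for a in A) / total

    prev = captured(U1, U2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P2 = U2 @ U2.T
        U1 = top_eigvecs(sum(a @ P2 @ a.T for a in A), d1)
        P1 = U1 @ U1.T
        U2 = top_eigvecs(sum(a.T @ P1 @ a for a in A), d2)
        cur = captured(U1, U2)
        if cur + 1e-12 < prev:
            raise AssertionError("captured variation decreased across an "
                                 "MPCA iteration (numerical fault)")
        if cur - prev < tol:
            converged = True
            prev = cur
            break
        prev = cur
    U1 = _fix_signs(U1)
    U2 = _fix_signs(U2)
    return MPCAResult(mode_projections=(U1, U2), captured_variation=prev,
                      mpc1_loadings=U1[:, 0], n_iter=it, converged=converged,
                      n_imputed=n_imputed)
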