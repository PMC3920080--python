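"""Paired statistics for lesion effects and scaffold extraction.

Node removals are tested metric-by-metric with a paired t test (healthy vs
lesioned values across subjects). Edge removals are tested with a paired
Hotelling T2 on the p=4 global feature vector, converted to an F statistic
via ``F = (N - p) T2 / [p (N - 1)]`` with ``F ~ F_{p, N-p}``; the null is
rejected when ``1 - cdf(F) < alpha / m`` with the Bonferroni denominator
``m = G(G-1)/2`` regardless of how many edges actually exist. The core
scaffold is the set of edges significant at that threshold, ranked by F.

Degenerate cases are surfaced, never silently inverted: a singular paired
covariance is handled with the Moore-Penrose pseudoinverse, using the
effective rank as the dimension in the F conversion and flagging the result;
edges with too few subjects showing any effect are reported non-testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from corescaffold.lesion_sweep import (EdgeLesionTable, NodeLesionTable,
                                       NODE_METRICS)
from corescaffold.parcellation_io import Parcellation


def bonferroni_threshold(alpha: float, m_comparisons: int) -> float:
    """Per-comparison significance level alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be a positive integer")
    return alpha / m_comparisons


@dataclass(frozen=True)
class NodeTestResult:
    parcel: int
    metric: str
    mean_healthy: float
    mean_lesioned: float
    sd_healthy: float
    sd_lesioned: float
    t: float
    p: float
    significant: bool
    degenerate: bool = False
    n_used: int = 0


def paired_t_node(table: NodeLesionTable, alpha: float = 0.05,
                  m_comparisons: Optional[int] = None,
                  ) -> list[NodeTestResult]:
    """Paired t test of intact vs lesioned values, per (parcel, metric).

    The tested difference is healthy minus lesioned; two-sided p values.
    ``m_comparisons`` defaults to n_lesions x n_metrics (each parcel/metric
    pair is one hypothesis). Zero-variance differences yield a degenerate
    flag (t undefined), reported rather than raised; subjects with an
    undefined (NaN) lesioned value are dropped pairwise.
    """
    if table.N < 3:
        raise ValueError("paired t test requires at least 3 subjects")
    if m_comparisons is None:
        m_comparisons = table.n_lesions * len(NODE_METRICS)
    level = bonferroni_threshold(alpha, m_comparisons)
    results = []
    for metric in NODE_METRICS:
        healthy = table.intact[metric]
        for li, parcel in enumerate(table.parcels):
            lesioned = table.lesioned[metric][li]
            ok = ~np.isnan(lesioned) & ~np.isnan(healthy)
            h, l = healthy[ok], lesioned[ok]
            n = int(ok.sum())
            d = h - l
            sd_d = d.std(ddof=1) if n > 1 else 0.0
            if n < 3 or sd_d == 0:
                degenerate = bool(np.any(d != 0)) or n < 3
                t = 0.0 if not degenerate else np.nan
                p = 1.0 if not degenerate else np.nan
                results.append(NodeTestResult(
                    parcel=int(parcel), metric=metric,
                    mean_healthy=float(h.mean()) if n else np.nan,
                    mean_lesioned=float(l.mean()) if n else np.nan,
                    sd_healthy=float(h.std(ddof=1)) if n > 1 else np.nan,
                    sd_lesioned=float(l.std(ddof=1)) if n > 1 else np.nan,
                    t=t, p=p, significant=False, degenerate=degenerate,
                    n_used=n))
                continue
            t = float(d.mean() / (sd_d / np.sqrt(n)))
            p = float(2.0 * stats.t.sf(abs(t), n - 1))
            results.append(NodeTestResult(
                parcel=int(parcel), metric=metric,
                mean_healthy=float(h.mean()), mean_lesioned=float(l.mean()),
                sd_healthy=float(h.std(ddof=1)),
                sd_lesioned=float(l.std(ddof=1)),
                t=t, p=p, significant=bool(p < level), n_used=n))
    return results


def t_score_table(results: Sequence[NodeTestResult]) -> pd.DataFrame:
    """Per-parcel t scores, one column per metric (for cortical maps)."""
    df = pd.DataFrame([(r.parcel, r.metric, r.t) for r in results],
                      columns=["parcel", "metric", "t"])
    return df.pivot(index="parcel", columns="metric", values="t")


@dataclass(frozen=True)
class HotellingResult:
    """Core of the paired multivariate test.

    ``df1`` is the effective dimension used in the F conversion (< p when the
    paired covariance was rank-deficient, in which case ``rank_deficient`` is
    set); ``n_used`` is the number of complete subject pairs.
    """

    T2: float
    F: float
    p: float
    df1: int
    df2: int
    n_used: int
    rank_deficient: bool = False
    n_dropped: int = 0


def hotelling_paired(lesioned: np.ndarray, intact: np.ndarray,
                     rank_tol: float = 1e-10) -> HotellingResult:
    """Paired Hotelling T2 for two N x p matrices of matched observations.

    Differences D = lesioned - intact; T2 = N d_bar' S^{-1} d_bar with S the
    sample covariance of D (divisor N-1); F = (N - p) T2 / [p (N - 1)],
    distributed as F_{p, N-p} under the null. Rows containing NaN in either
    matrix are dropped pairwise (``n_dropped``). A singular S is handled via
    its eigendecomposition: directions with relative variance below
    ``rank_tol`` are excluded and the effective rank replaces p.
    """
    lesioned = np.atleast_2d(np.asarray(lesioned, dtype=float))
    intact = np.atleast_2d(np.asarray(intact, dtype=float))
    if lesioned.shape != intact.shape:
        raise ValueError("lesioned and intact must have identical shape")
    N_all, p = lesioned.shape
    D = lesioned - intact
    complete = ~np.isnan(D).any(axis=1)
    D = D[complete]
    N = D.shape[0]
    n_dropped = N_all - N
    if N <= p:
        raise ValueError(f"need more than p={p} complete subject pairs, "
                         f"got N={N}")
    dbar = D.mean(axis=0)
    if np.all(D == 0):
        return HotellingResult(T2=0.0, F=0.0, p=1.0, df1=p, df2=N - p,
                               n_used=N, n_dropped=n_dropped)
    S = np.cov(D, rowvar=False, ddof=1).reshape(p, p)
    evals, evecs = np.linalg.eigh(S)
    # a direction whose variance is negligible relative both to the largest
    # variance and to the mean difference magnitude is treated as constant
    scale = max(evals.max(), float(dbar @ dbar), np.finfo(float).tiny)
    keep = evals > rank_tol * scale
    r = int(keep.sum())
    rank_deficient = r < p
    if r == 0:
        # all differences constant across subjects: no sampling variance to
        # test against -> degenerate, reported as non-significant
        return HotellingResult(T2=0.0, F=0.0, p=1.0, df1=0, df2=N - 1,
                               n_used=N, rank_deficient=True,
                               n_dropped=n_dropped)
    z = evecs[:, keep].T @ dbar
    T2 = float(N * np.sum(z * z / evals[keep]))
    F = (N - r) * T2 / (r * (N - 1))
    pval = float(stats.f.sf(F, r, N - r))
    return HotellingResult(T2=T2, F=float(F), p=pval, df1=r, df2=N - r,
                           n_used=N, rank_deficient=rank_deficient,
                           n_dropped=n_dropped)


@dataclass(frozen=True)
class EdgeTestResult:
    pair: tuple[int, int]
    T2: float
    F: float
    p: float
    significant: bool
    n_nonzero_diff: int
    testable: bool
    df1: int = 0
    df2: int = 0
    rank_deficient: bool = False


def edge_significance(table: EdgeLesionTable, alpha: float = 0.05,
                      m_comparisons: Optional[int] = None,
                      ) -> list[EdgeTestResult]:
    """One paired Hotelling test per unordered node pair.

    ``m_comparisons`` defaults to the number of possible pairs G(G-1)/2
    (every possible connection is one comparison, whether or not the edge
    exists in any subject). Pairs whose difference vectors are all zero
    (edge absent in every subject) and pairs with fewer than p+2 subjects
    showing any effect are reported non-testable and never significant.
    """
    if m_comparisons is None:
        m_comparisons = table.n_pairs
    level = bonferroni_threshold(alpha, m_comparisons)
    p_dim = table.lesioned.shape[2]
    results = []
    for pi in range(table.n_pairs):
        L = table.lesioned[pi]
        D = L - table.intact
        with np.errstate(invalid="ignore"):
            nonzero = int(np.sum(np.any((D != 0) & ~np.isnan(D), axis=1)))
        if nonzero == 0:
            results.append(EdgeTestResult(
                pair=tuple(int(x) for x in table.pairs[pi]),
                T2=0.0, F=0.0, p=1.0, significant=False,
                n_nonzero_diff=0, testable=False))
            continue
        core = hotelling_paired(L, table.intact)
        testable = nonzero >= p_dim + 2
        results.append(EdgeTestResult(
            pair=tuple(int(x) for x in table.pairs[pi]),
            T2=core.T2, F=core.F, p=core.p,
            significant=bool(testable and core.p < level),
            n_nonzero_diff=nonzero, testable=testable,
            df1=core.df1, df2=core.df2,
            rank_deficient=core.rank_deficient))
    return results


def extract_scaffold(edge_results: Sequence[EdgeTestResult],
                     alpha: float = 0.05,
                     m_comparisons: Optional[int] = None,
                     ) -> list[EdgeTestResult]:
    """Edges whose removal significantly perturbs the feature vector.

    Re-thresholds the per-edge p values at ``alpha / m`` (so one sweep can be
    cut at both the lenient alpha=0.05 scaffold and the stringent
    alpha=0.0001 core) and returns them sorted by descending F. Shrinking
    alpha can only shrink the returned set.
    """
    if m_comparisons is None:
        m_comparisons = len(edge_results)
    level = bonferroni_threshold(alpha, m_comparisons)
    hits = [r for r in edge_results if r.testable and r.p < level]
    return sorted(hits, key=lambda r: -r.F)


def edge_results_frame(edge_results: Sequence[EdgeTestResult],
                       parcellation: Optional[Parcellation] = None,
                       ) -> pd.DataFrame:
    labels = parcellation.labels if parcellation is not None else None
    rows = []
    for r in edge_results:
        i, j = r.pair
        rows.append(((labels[i] if labels else i),
                     (labels[j] if labels else j),
                     r.T2, r.F, r.p, r.significant, r.n_nonzero_diff,
                     r.testable, r.rank_deficient))
    return pd.DataFrame(rows, columns=[
        "parcel_a", "parcel_b", "T2", "F", "p", "significant",
        "n_nonzero_diff", "testable", "rank_deficient"])


def write_circos_links(scaffold: Sequence[EdgeTestResult],
                       parcellation: Parcellation, path) -> None:
    """Circos-compatible link file (parcel_a, parcel_b, F) for the scaffold."""
    labels = parcellation.labels
    with open(path, "w") as fh:
        fh.write("parcel_a\tparcel_b\tF\n")
        for r in scaffold:
            i, j = r.pair
            fh.write(f"{labels[i]}\t{labels[j]}\t{r.F:.6g}\n")
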