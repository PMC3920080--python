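"""Synthetic cohorts of weighted connectomes with planted critical edges.

Real tractography cohorts are not redistributable, so every downstream stage
is exercised on generated data with the statistical structure the analysis
assumes: a planted-partition modular base topology shared by all subjects,
log-normal base weights, strong planted inter-module bridge edges (the
ground-truth "core scaffold"), weak ordinary between-module connections, and
independent multiplicative log-normal inter-subject noise. Each subject's
matrix is normalized so its upper-triangle sum is 1, like a fiber-count
fraction matrix.

Why these defaults: connectomes are locally dense and redundant (removing
one short-range connection barely changes path structure), long-range
connections are comparatively weak (streamline counts attenuate with
distance) except for a few strong bundles, and inter-subject variability of
streamline counts is large. These features are exactly what makes the
planted bridges - and only them - statistically critical, giving a
controllable ground truth for scaffold recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import yaml
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from corescaffold.parcellation_io import (Cohort, Connectome, Parcellation,
                                          index_parcellation)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort; equal specs generate equal cohorts.

    ``weight_log_mean`` / ``weight_log_sd`` parameterize the log-normal base
    weight of present edges; ``subject_noise_sd`` the per-subject,
    per-edge multiplicative log-normal noise; ``between_weight_factor``
    scales ordinary between-module weights down (weak long-range
    connections); planted bridges are forced present in every subject with
    their base draw multiplied by ``planted_boost``. ``edge_dropout``
    optionally removes each non-planted edge per subject with that
    probability (off by default: subjects share one base topology).
    ``symmetry_rho`` correlates the noise on homotopic left/right edges when
    the parcellation has two hemispheres.
    """

    G: Optional[int] = None
    parcellation: Optional[Parcellation] = None
    n_subjects: int = 110
    n_modules: int = 4
    p_within: float = 0.85
    p_between: float = 0.03
    weight_log_mean: float = 0.0
    weight_log_sd: float = 0.15
    subject_noise_sd: float = 0.9
    between_weight_factor: float = 0.2
    planted_edges: tuple[tuple[int, int], ...] = ()
    planted_boost: float = 5.0
    edge_dropout: float = 0.0
    symmetry_rho: float = 0.0
    ensure_connected: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.parcellation is None and self.G is None:
            raise ValueError("provide either G or a parcellation")
        if self.parcellation is not None and self.G is not None \
                and self.parcellation.G != self.G:
            raise ValueError("G disagrees with the parcellation size")
        G = self.resolved_G
        if G < 4:
            raise ValueError("G must be at least 4")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.n_modules < 2:
            raise ValueError("n_modules must be at least 2")
        if not (0 < self.p_within <= 1):
            raise ValueError("p_within must lie in (0, 1]")
        if not (0 <= self.p_between < 1):
            raise ValueError("p_between must lie in [0, 1)")
        if not (0 <= self.edge_dropout < 1):
            raise ValueError("edge_dropout must lie in [0, 1)")
        if not (0 <= self.symmetry_rho <= 1):
            raise ValueError("symmetry_rho must lie in [0, 1]")
        if self.planted_boost < 1:
            raise ValueError("planted_boost must be >= 1")
        norm = tuple(tuple(sorted((int(i), int(j)))) for i, j in self.planted_edges)
        for i, j in norm:
            if i == j or not (0 <= i < G and 0 <= j < G):
                raise ValueError(f"invalid planted edge ({i}, {j})")
        if len(set(norm)) != len(norm):
            raise ValueError("duplicate planted edges")
        object.__setattr__(self, "planted_edges", norm)

    @property
    def resolved_G(self) -> int:
        return self.parcellation.G if self.parcellation is not None else self.G

    def resolve_parcellation(self) -> Parcellation:
        if self.parcellation is not None:
            return self.parcellation
        return index_parcellation(self.G)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d.pop("parcellation")
        d["planted_edges"] = [list(e) for e in self.planted_edges]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["planted_edges"] = tuple(tuple(e) for e in d.get("planted_edges", ()))
        return cls(**d)


def modules(spec: CohortSpec) -> np.ndarray:
    """Module label per node (contiguous, nearly equal blocks)."""
    G = spec.resolved_G
    sizes = [len(b) for b in np.array_split(np.arange(G), spec.n_modules)]
    return np.repeat(np.arange(spec.n_modules), sizes)


def default_bridges(G: int, n_modules: int, n_planted: int, seed: int = 0,
                    ) -> tuple[tuple[int, int], ...]:
    """Deterministically choose cross-module node pairs to plant as bridges.

    Cycles over module pairs so every pair of modules receives a bridge
    before any receives a second one.
    """
    spec_mod = np.repeat(
        np.arange(n_modules),
        [len(b) for b in np.array_split(np.arange(G), n_modules)])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9e3779b9]))
    pairs = list(itertools.combinations(range(n_modules), 2))
    chosen: list[tuple[int, int]] = []
    for t in range(n_planted):
        ma, mb = pairs[t % len(pairs)]
        while True:
            i = int(rng.choice(np.flatnonzero(spec_mod == ma)))
            j = int(rng.choice(np.flatnonzero(spec_mod == mb)))
            e = (min(i, j), max(i, j))
            if e not in chosen:
                chosen.append(e)
                break
    return tuple(chosen)


def planted_truth(spec: CohortSpec) -> list[tuple[int, int]]:
    """Ground-truth critical edges (as sorted node pairs)."""
    return [tuple(e) for e in spec.planted_edges]


def _base_graph(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    G = spec.resolved_G
    mod = modules(spec)
    planted = set(spec.planted_edges)
    W = np.zeros((G, G))
    iu = np.triu_indices(G, 1)
    same = mod[iu[0]] == mod[iu[1]]
    prob = np.where(same, spec.p_within, spec.p_between)
    present = rng.random(prob.size) < prob
    w = rng.lognormal(spec.weight_log_mean, spec.weight_log_sd, size=prob.size)
    w *= np.where(same, 1.0, spec.between_weight_factor)
    w *= present
    W[iu] = w
    W = W + W.T
    for (i, j) in planted:
        W[i, j] = W[j, i] = (
            rng.lognormal(spec.weight_log_mean, spec.weight_log_sd)
            * spec.planted_boost)
    if spec.ensure_connected:
        W = _connect(W, spec, rng)
    return W


def _connect(W: np.ndarray, spec: CohortSpec,
             rng: np.random.Generator) -> np.ndarray:
    n_comp, labels = connected_components(csr_matrix(W > 0), directed=False)
    if n_comp == 1:
        return W
    W = W.copy()
    pos = W[W > 0]
    fill = float(np.median(pos)) if pos.size else float(
        np.exp(spec.weight_log_mean))
    anchor = int(np.flatnonzero(labels == labels[0])[0])
    for c in range(n_comp):
        if c == labels[0]:
            continue
        other = int(np.flatnonzero(labels == c)[0])
        W[anchor, other] = W[other, anchor] = fill
    return W


def _homotopic_edge_map(parcellation: Parcellation) -> Optional[np.ndarray]:
    """Index of each node's opposite-hemisphere twin, or None."""
    twin = np.full(parcellation.G, -1)
    by_key = {}
    for p in parcellation.parcels:
        by_key[(p.hemisphere, p.lobe, p.ap_rank)] = p.id
    found = False
    for p in parcellation.parcels:
        opp = {"left": "right", "right": "left"}.get(p.hemisphere)
        if opp is None:
            continue
        t = by_key.get((opp, p.lobe, p.ap_rank))
        if t is not None:
            twin[p.id] = t
            found = True
    return twin if found else None


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the cohort: one base topology, per-subject weight noise.

    Reproducible: the same spec (including seed) yields an identical cohort;
    subject streams are independent substreams of the master seed, so the
    cohort is also independent of subject iteration order.
    """
    parcellation = spec.resolve_parcellation()
    G = parcellation.G
    master = np.random.SeedSequence(spec.seed)
    topo_ss, *subject_ss = master.spawn(1 + spec.n_subjects)
    base = _base_graph(spec, np.random.default_rng(topo_ss))
    iu = np.triu_indices(G, 1)
    planted_mask = np.zeros((G, G), dtype=bool)
    for (i, j) in spec.planted_edges:
        planted_mask[i, j] = planted_mask[j, i] = True
    twin = (_homotopic_edge_map(parcellation)
            if spec.symmetry_rho > 0 else None)
    subjects = []
    for n, ss in enumerate(subject_ss):
        rng = np.random.default_rng(ss)
        log_noise = rng.normal(0.0, spec.subject_noise_sd, size=iu[0].size)
        if twin is not None:
            log_noise = _mix_homotopic(log_noise, iu, twin,
                                       spec.symmetry_rho, rng,
                                       spec.subject_noise_sd)
        noise = np.zeros((G, G))
        noise[iu] = np.exp(log_noise)
        noise = noise + noise.T
        W = base * noise
        if spec.edge_dropout > 0:
            drop = np.zeros((G, G), dtype=bool)
            drop[iu] = rng.random(iu[0].size) < spec.edge_dropout
            drop |= drop.T
            drop &= ~planted_mask
            W = np.where(drop, 0.0, W)
        total = W[iu].sum()
        if total == 0:
            raise RuntimeError("generated subject has no edges")
        subjects.append(Connectome(subject_id=f"sub{n:03d}",
                                   weights=W / total,
                                   parcellation=parcellation))
    return Cohort(subjects=tuple(subjects), parcellation=parcellation)


def _mix_homotopic(log_noise: np.ndarray, iu, twin: np.ndarray, rho: float,
                   rng: np.random.Generator, sd: float) -> np.ndarray:
    """Correlate noise on homotopic edge pairs with coefficient rho."""
    edge_index = {}
    for e, (i, j) in enumerate(zip(*iu)):
        edge_index[(int(i), int(j))] = e
    shared = rng.normal(0.0, sd, size=log_noise.size)
    out = log_noise.copy()
    for e, (i, j) in enumerate(zip(*iu)):
        ti, tj = twin[i], twin[j]
        if ti < 0 or tj < 0:
            continue
        te = edge_index.get((min(ti, tj), max(ti, tj)))
        if te is None or te < e:
            continue  # handle each homotopic pair once, from the lower index
        common = shared[e]
        out[e] = (np.sqrt(rho) * common
                  + np.sqrt(1 - rho) * log_noise[e])
        out[te] = (np.sqrt(rho) * common
                   + np.sqrt(1 - rho) * log_noise[te])
    return out
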