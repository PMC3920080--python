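"""Parcellation data model and connectome I/O.

Defines the node identity of every network: an ordered catalogue of brain
parcels (hemisphere, lobe, antero-posterior rank) that fixes the row/column
ordering of all connectivity matrices, plus readers/writers for the
tab-separated on-disk formats and the per-cohort directory bundle.

Matrix ordering convention: right hemisphere first, then left, lobes in a
fixed order and parcels in antero-posterior rank within each lobe; the
midline brainstem comes last. This makes correlation matrices directly
inspectable for anatomical patterns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from corescaffold.exceptions import CoreScaffoldError

HEMISPHERES = ("right", "left", "midline")

#: The six cortical lobes; parcels in any of them count as cortical.
CORTICAL_LOBES = ("frontal", "insula", "limbic", "temporal", "parietal", "occipital")

NONCORTICAL_LOBES = ("subcortical", "cerebellum", "brainstem")

LOBES = CORTICAL_LOBES + NONCORTICAL_LOBES

#: Parcels per cortical lobe in one hemisphere of the default scheme.
DEFAULT_LOBE_COUNTS = {
    "frontal": 21,
    "insula": 8,
    "limbic": 8,
    "temporal": 11,
    "parietal": 11,
    "occipital": 15,
}

_LOBE_ABBREV = {
    "frontal": "Fro",
    "insula": "Ins",
    "limbic": "Lim",
    "temporal": "Tem",
    "parietal": "Par",
    "occipital": "Occ",
    "subcortical": "Sub",
    "cerebellum": "Cer",
    "brainstem": "Bst",
}


@dataclass(frozen=True)
class Parcel:
    """One brain parcel (graph node).

    ``id`` is the 0-based position in the matrix ordering; ``ap_rank`` is the
    antero-posterior order of the parcel within its lobe.
    """

    id: int
    label: str
    hemisphere: str
    lobe: str
    ap_rank: int

    def __post_init__(self):
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.lobe not in LOBES:
            raise ValueError(f"unknown lobe {self.lobe!r}")

    @property
    def is_cortical(self) -> bool:
        return self.lobe in CORTICAL_LOBES


@dataclass(frozen=True)
class Parcellation:
    """Ordered catalogue of parcels defining node identity and matrix order."""

    parcels: tuple[Parcel, ...]

    def __post_init__(self):
        ids = [p.id for p in self.parcels]
        if ids != list(range(len(self.parcels))):
            raise ValueError("parcel ids must be the contiguous sequence 0..G-1 "
                             "in matrix order")
        labels = [p.label for p in self.parcels]
        if len(set(labels)) != len(labels):
            raise ValueError("parcel labels must be unique")

    @property
    def G(self) -> int:
        return len(self.parcels)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.parcels]

    def cortical_ids(self) -> list[int]:
        """Ids of cortical parcels (the lesionable nodes), in matrix order."""
        return [p.id for p in self.parcels if p.is_cortical]

    def __eq__(self, other) -> bool:
        return isinstance(other, Parcellation) and self.parcels == other.parcels

    def __hash__(self):
        return hash(self.parcels)


def default_parcellation() -> Parcellation:
    """The default 165-parcel whole-brain scheme.

    Per hemisphere: 74 cortical parcels (frontal 21, insula 8, limbic 8,
    temporal 11, parietal 11, occipital 15), 7 subcortical parcels and the
    cerebellum; plus one midline brainstem. Right hemisphere is listed first,
    lobes in the order above, parcels in antero-posterior order within each
    lobe. Labels are systematic placeholders (e.g. ``rFro01``); the anatomical
    abbreviations of a specific atlas may be supplied via a user parcel table.
    """
    parcels: list[Parcel] = []
    for hemi, prefix in (("right", "r"), ("left", "l")):
        for lobe in CORTICAL_LOBES:
            for k in range(DEFAULT_LOBE_COUNTS[lobe]):
                parcels.append(Parcel(
                    id=len(parcels),
                    label=f"{prefix}{_LOBE_ABBREV[lobe]}{k + 1:02d}",
                    hemisphere=hemi,
                    lobe=lobe,
                    ap_rank=k,
                ))
        for k in range(7):
            parcels.append(Parcel(
                id=len(parcels), label=f"{prefix}Sub{k + 1:02d}",
                hemisphere=hemi, lobe="subcortical", ap_rank=k))
        parcels.append(Parcel(
            id=len(parcels), label=f"{prefix}Cer01",
            hemisphere=hemi, lobe="cerebellum", ap_rank=0))
    parcels.append(Parcel(
        id=len(parcels), label="mBst01",
        hemisphere="midline", lobe="brainstem", ap_rank=0))
    return Parcellation(tuple(parcels))


def index_parcellation(G: int, lobe: str = "frontal") -> Parcellation:
    """A reduced G-node parcellation for simulation studies.

    All parcels are placed in one cortical lobe of the right hemisphere, so
    every node is lesionable. Used by the synthetic-cohort generator when a
    full anatomical scheme is not needed.
    """
    if G < 1:
        raise ValueError("G must be positive")
    return Parcellation(tuple(
        Parcel(id=i, label=f"n{i:03d}", hemisphere="right", lobe=lobe, ap_rank=i)
        for i in range(G)
    ))


def _check_weights(weights: np.ndarray, G: Optional[int] = None) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise ValueError(f"weights must be square, got shape {weights.shape}")
    if G is not None and weights.shape[0] != G:
        raise ValueError(
            f"matrix is {weights.shape[0]}x{weights.shape[0]} but the "
            f"parcellation has {G} parcels")
    if not np.all(np.isfinite(weights)):
        raise ValueError("weights contain non-finite entries")
    if np.any(weights < 0):
        raise ValueError("weights contain negative entries")
    if not np.array_equal(weights, weights.T):
        raise ValueError("weights matrix is asymmetric; refusing to "
                         "symmetrize silently")
    if np.any(np.diag(weights) != 0):
        raise ValueError("weights diagonal must be exactly zero")
    return weights


def _check_companion(name: str, mat, weights: np.ndarray) -> Optional[np.ndarray]:
    if mat is None:
        return None
    mat = np.asarray(mat, dtype=float)
    if mat.shape != weights.shape:
        raise ValueError(f"{name} matrix shape {mat.shape} != weights shape "
                         f"{weights.shape}")
    if np.any((weights == 0) & (mat != 0)):
        raise ValueError(f"{name} defined where weight is zero")
    return mat


@dataclass(frozen=True)
class Connectome:
    """One subject's weighted, undirected, zero-diagonal connectivity matrix.

    ``weights`` holds normalized fiber-count fractions or raw counts;
    optional ``lengths`` (mean fiber length, cm) and ``fa`` (mean fractional
    anisotropy) companions are defined only where ``weights > 0``.
    ``node_ids`` maps matrix rows to parcel ids of ``parcellation`` and
    differs from 0..G-1 only for node-lesioned (sub-)networks.
    """

    subject_id: str
    weights: np.ndarray
    lengths: Optional[np.ndarray] = None
    fa: Optional[np.ndarray] = None
    parcellation: Optional[Parcellation] = None
    node_ids: Optional[np.ndarray] = None

    def __post_init__(self):
        G = None
        if self.parcellation is not None and self.node_ids is None:
            G = self.parcellation.G
        weights = _check_weights(self.weights, G)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "lengths",
                           _check_companion("lengths", self.lengths, weights))
        object.__setattr__(self, "fa", _check_companion("fa", self.fa, weights))
        if self.fa is not None and np.any((self.fa < 0) | (self.fa > 1)):
            raise ValueError("fa entries must lie in [0, 1]")
        if self.node_ids is not None:
            ids = np.asarray(self.node_ids, dtype=int)
            if ids.shape != (weights.shape[0],):
                raise ValueError("node_ids length must match matrix size")
            object.__setattr__(self, "node_ids", ids)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def original_ids(self) -> np.ndarray:
        """Parcel ids of the rows (identity unless node-lesioned)."""
        if self.node_ids is not None:
            return self.node_ids
        return np.arange(self.n_nodes)

    def with_weights(self, weights: np.ndarray) -> "Connectome":
        return replace(self, weights=weights)


@dataclass(frozen=True)
class Cohort:
    """N connectomes sharing one parcellation; the unit of all statistics."""

    subjects: tuple[Connectome, ...]
    parcellation: Parcellation

    def __post_init__(self):
        if len(self.subjects) == 0:
            raise ValueError("cohort is empty")
        for c in self.subjects:
            if c.parcellation is not None and c.parcellation != self.parcellation:
                raise ValueError("mixed parcellations in cohort")
            if c.n_nodes != self.parcellation.G:
                raise ValueError("subject matrix size does not match parcellation")

    @property
    def N(self) -> int:
        return len(self.subjects)

    @property
    def G(self) -> int:
        return self.parcellation.G

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)

    def __getitem__(self, i):
        return self.subjects[i]


def cohort_average(cohort: Cohort) -> Connectome:
    """Entrywise mean connectome across subjects (probabilistic connectivity)."""
    stack = np.stack([c.weights for c in cohort.subjects])
    return Connectome(subject_id="cohort_average",
                      weights=stack.mean(axis=0),
                      parcellation=cohort.parcellation)


# ---------------------------------------------------------------------------
# On-disk formats. Connectome matrices: TSV, full square matrix with a header
# row of parcel labels; written with 17 significant digits so a write->read
# round trip is bit-exact. Parcel metadata: TSV with columns id, label,
# hemisphere, lobe, ap_rank.
# ---------------------------------------------------------------------------

def write_parcel_table(parcellation: Parcellation, path) -> None:
    df = pd.DataFrame(
        [(p.id, p.label, p.hemisphere, p.lobe, p.ap_rank)
         for p in parcellation.parcels],
        columns=["id", "label", "hemisphere", "lobe", "ap_rank"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_parcel_table(path) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "label", "hemisphere", "lobe", "ap_rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parcel table missing columns: {sorted(missing)}")
    parcels = tuple(
        Parcel(id=int(r.id), label=str(r.label), hemisphere=str(r.hemisphere),
               lobe=str(r.lobe), ap_rank=int(r.ap_rank))
        for r in df.sort_values("id").itertuples()
    )
    return Parcellation(parcels)


def _write_matrix(mat: np.ndarray, labels: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in mat:
            fh.write("\t".join(f"{x:.17g}" for x in row) + "\n")


def _read_matrix(path, labels: Sequence[str]) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if header != list(labels):
        raise ValueError(f"{path}: header labels do not match the parcel table")
    mat = np.array(rows, dtype=float)
    if mat.shape != (len(labels), len(labels)):
        raise ValueError(f"{path}: expected a {len(labels)}x{len(labels)} matrix, "
                         f"got {mat.shape}")
    return mat


def write_connectome(connectome: Connectome, path) -> None:
    """Write the weights matrix as TSV (label header + full square matrix).

    Companion ``lengths`` / ``fa`` matrices, when present, go to sibling
    files with ``.lengths.tsv`` / ``.fa.tsv`` suffixes.
    """
    path = Path(path)
    labels = (connectome.parcellation.labels if connectome.parcellation
              else [f"n{i:03d}" for i in range(connectome.n_nodes)])
    _write_matrix(connectome.weights, labels, path)
    if connectome.lengths is not None:
        _write_matrix(connectome.lengths, labels,
                      path.with_suffix(".lengths.tsv"))
    if connectome.fa is not None:
        _write_matrix(connectome.fa, labels, path.with_suffix(".fa.tsv"))


def read_connectome(matrix_file, parcel_table, subject_id: Optional[str] = None,
                    ) -> Connectome:
    """Read a connectome from a TSV matrix plus a parcel metadata table.

    ``parcel_table`` may be a path or an already-loaded :class:`Parcellation`.
    Symmetry and the zero diagonal are enforced on read: asymmetric input is
    rejected, never silently symmetrized.
    """
    matrix_file = Path(matrix_file)
    if isinstance(parcel_table, Parcellation):
        parcellation = parcel_table
    else:
        parcellation = read_parcel_table(parcel_table)
    weights = _read_matrix(matrix_file, parcellation.labels)
    lengths = fa = None
    lf = matrix_file.with_suffix(".lengths.tsv")
    if lf.exists():
        lengths = _read_matrix(lf, parcellation.labels)
    ff = matrix_file.with_suffix(".fa.tsv")
    if ff.exists():
        fa = _read_matrix(ff, parcellation.labels)
    if subject_id is None:
        subject_id = matrix_file.stem
    return Connectome(subject_id=subject_id, weights=weights, lengths=lengths,
                      fa=fa, parcellation=parcellation)


# ---------------------------------------------------------------------------
# Cohort bundle: a directory with parcels.tsv, one <subject>.tsv per subject
# and a manifest fixing subject order.
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_parcel_table(cohort.parcellation, directory / "parcels.tsv")
    manifest = {"subjects": [c.subject_id for c in cohort.subjects]}
    for c in cohort.subjects:
        write_connectome(c, directory / f"{c.subject_id}.tsv")
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_cohort(directory) -> Cohort:
    directory = Path(directory)
    parcellation = read_parcel_table(directory / "parcels.tsv")
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    subjects = tuple(
        read_connectome(directory / f"{sid}.tsv", parcellation, subject_id=sid)
        for sid in manifest["subjects"]
    )
    return Cohort(subjects=subjects, parcellation=parcellation)
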