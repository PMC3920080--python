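"""Build per-subject connectivity matrices from a streamline-endpoint table.

Each streamline (fiber) is a record of its two endpoint parcels, its length
in cm and its mean fractional anisotropy. Fibers shorter than 1.5 cm are
discarded, as are fibers that start and end in the same parcel; surviving
fibers increment the count for their parcel pair, and mean length / mean FA
companions are accumulated alongside. Per-subject normalization divides each
count by the subject's total surviving fiber count so the upper-triangle sum
of the weights equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from corescaffold.parcellation_io import Connectome, Parcellation

#: Default minimum streamline length retained, in cm (strict: < is discarded,
#: exactly 1.5 cm is retained).
MIN_FIBER_LENGTH_CM = 1.5


@dataclass(frozen=True)
class FiberRecord:
    """One reconstructed streamline: endpoint parcels, length (cm), mean FA."""

    parcel_a: int
    parcel_b: int
    length_cm: float
    fa: float

    def __post_init__(self):
        if not self.length_cm > 0:
            raise ValueError("length_cm must be positive")
        if not (0.0 <= self.fa <= 1.0):
            raise ValueError("fa must lie in [0, 1]")


def read_fiber_table(path) -> list[FiberRecord]:
    """Read a TSV with columns parcel_a, parcel_b, length_cm, fa."""
    df = pd.read_csv(path, sep="\t")
    return [FiberRecord(int(r.parcel_a), int(r.parcel_b),
                        float(r.length_cm), float(r.fa))
            for r in df.itertuples()]


def build_connectome(fiber_table: Iterable[FiberRecord],
                     parcellation: Parcellation,
                     min_length_cm: float = MIN_FIBER_LENGTH_CM,
                     subject_id: str = "subject") -> Connectome:
    """Aggregate fiber records into count / mean-length / mean-FA matrices.

    Records with ``length_cm < min_length_cm`` or with both endpoints in the
    same parcel are excluded. An empty table yields the valid zero connectome.
    """
    G = parcellation.G
    counts = np.zeros((G, G))
    length_sum = np.zeros((G, G))
    fa_sum = np.zeros((G, G))
    for rec in fiber_table:
        if not (0 <= rec.parcel_a < G and 0 <= rec.parcel_b < G):
            raise ValueError(
                f"fiber endpoints ({rec.parcel_a}, {rec.parcel_b}) outside "
                f"the {G}-parcel scheme")
        if rec.length_cm < min_length_cm or rec.parcel_a == rec.parcel_b:
            continue
        i, j = rec.parcel_a, rec.parcel_b
        counts[i, j] += 1
        counts[j, i] += 1
        length_sum[i, j] += rec.length_cm
        length_sum[j, i] += rec.length_cm
        fa_sum[i, j] += rec.fa
        fa_sum[j, i] += rec.fa
    with np.errstate(invalid="ignore"):
        lengths = np.where(counts > 0, length_sum / np.maximum(counts, 1), 0.0)
        fa = np.where(counts > 0, fa_sum / np.maximum(counts, 1), 0.0)
    return Connectome(subject_id=subject_id, weights=counts, lengths=lengths,
                      fa=fa, parcellation=parcellation)


def normalize_connectome(connectome: Connectome) -> Connectome:
    """Divide weights by the subject's total fiber count.

    The denominator is the sum of weights over unordered pairs (each
    anatomical connection counted once), which for count matrices equals the
    number of surviving fibers; afterwards the upper-triangle sum is 1.
    Lengths/FA companions are unchanged. Idempotent on already-normalized
    input up to floating point.
    """
    iu = np.triu_indices(connectome.n_nodes, 1)
    total = connectome.weights[iu].sum()
    if total == 0:
        raise ValueError("cannot normalize an all-zero connectome "
                         "(no fibers survive)")
    return connectome.with_weights(connectome.weights / total)
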