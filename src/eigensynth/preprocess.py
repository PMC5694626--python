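"""Intensity normalization to the maximum.

Nuclear-imaging intensities (dopamine-transporter binding in DaTSCAN,
glucose metabolism in FDG-PET) are only comparable across subjects after
correcting individual differences in uptake and acquisition. Each subject
is divided by I_n, the average of its top-fraction (default 3%) in-mask
intensities, so that after normalization the mean of the top-fraction
voxels is exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io_imaging import VoxelDataset

__all__ = ["NormalizationRecord", "NormalizationError", "normalize_to_max", "top_fraction_mean"]


class NormalizationError(ValueError):
    """A subject cannot be normalized (no positive signal)."""


@dataclass(frozen=True)
class NormalizationRecord:
    """Per-subject normalizer I_n and the top fraction used."""

    subject_id: str
    normalizer: float
    fraction: float

    def __post_init__(self) -> None:
        if not self.normalizer > 0:
            raise NormalizationError(
                f"subject {self.subject_id}: normalizer must be positive, "
                f"got {self.normalizer}"
            )


def top_fraction_mean(values: np.ndarray, fraction: float) -> float:
    """Mean of the ceil(fraction * N) largest values (at least one value).

    Selection is by count on the sorted array, so boundary ties are
    resolved deterministically.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise NormalizationError("cannot take top fraction of an empty vector")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = max(1, math.ceil(fraction * values.size))
    top = np.partition(values, values.size - k)[values.size - k:]
    return float(top.mean())


def normalize_to_max(
    dataset: VoxelDataset, fraction: float = 0.03
) -> tuple[VoxelDataset, list[NormalizationRecord]]:
    """Divide each subject by the mean of its top-fraction in-mask voxels.

    Properties: scale-equivariant (normalizing c*I equals normalizing I),
    idempotent, and rank-preserving within a subject.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    records: list[NormalizationRecord] = []
    out = np.empty_like(dataset.data)
    for i in range(dataset.n_subjects):
        row = dataset.data[i]
        if not (row > 0).any():
            raise NormalizationError(
                f"subject {dataset.subject_ids[i]} has no strictly positive voxel"
            )
        normalizer = top_fraction_mean(row, fraction)
        records.append(
            NormalizationRecord(
                subject_id=str(dataset.subject_ids[i]),
                normalizer=normalizer,
                fraction=fraction,
            )
        )
        out[i] = row / normalizer
    normalized = replace(dataset, data=out)
    return normalized, records
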