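"""Eigenbrain decomposition: PCA of the image stack via economy SVD.

The centered subjects x voxels matrix X (dataset-global voxelwise mean
subtracted) is factored as X = U S V^T. The columns of W = V are the
eigenbrains — an orthonormal basis of inter-subject variance modes — and
the latent scores are S = X W = U S. Truncation to the leading L
components gives S_L = X W_L; reconstruction is X_hat = S_L W_L^T + mean,
exact at L = rank (the full N x N covariance is never materialized).

Sign convention: each eigenbrain is flipped so its largest-magnitude
loading is positive, which makes the basis reproducible across SVD
implementations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_imaging import VolumeGeometry, VoxelDataset, unflatten, write_volume

__all__ = [
    "EigenbrainModel",
    "ScoreMatrix",
    "InsufficientDataError",
    "TruncationError",
    "fit_eigenbrains",
    "project",
    "reconstruct",
    "clip_nonnegative",
    "save_model",
    "load_model",
]

#: singular values below max(sv) * this are treated as numerically zero rank
_RANK_RTOL = 1e-10


class InsufficientDataError(ValueError):
    """Too few subjects (or zero variance) to build a basis."""


class TruncationError(ValueError):
    """Requested more components than the model's rank."""


@dataclass
class EigenbrainModel:
    """Mean image, orthonormal eigenbrain basis W, singular values, and L."""

    mean: np.ndarray            # length-N
    basis: np.ndarray           # N x M, orthonormal columns
    singular_values: np.ndarray  # length-M, nonincreasing, > 0
    L: int
    mask: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.basis = np.asarray(self.basis, dtype=np.float64)
        self.singular_values = np.asarray(self.singular_values, dtype=np.float64).ravel()
        if self.basis.shape != (self.mean.size, self.singular_values.size):
            raise ValueError("basis must be N x M with M singular values")
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be nonincreasing")
        if not 1 <= self.L <= self.M:
            raise TruncationError(f"L={self.L} outside 1..{self.M}")

    @property
    def n_voxels(self) -> int:
        return self.mean.size

    @property
    def M(self) -> int:
        return self.singular_values.size

    def eigenbrain_volume(self, component: int) -> np.ndarray:
        """One basis column as a 3D volume, for inspection/export."""
        return unflatten(self.basis[:, component], self.mask, self.geometry)


@dataclass
class ScoreMatrix:
    """Latent coordinates (K x L) of subjects in the eigenbrain space."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.scores.shape[0],):
            raise ValueError("labels must have one entry per score row")

    @property
    def L(self) -> int:
        return self.scores.shape[1]

    def class_scores(self, class_id) -> np.ndarray:
        idx = np.flatnonzero(self.labels == class_id)
        if idx.size == 0:
            raise KeyError(f"no scores with class {class_id!r}")
        return self.scores[idx]


def fit_eigenbrains(dataset: VoxelDataset, L: int | None = None) -> EigenbrainModel:
    """PCA of the dataset via economy SVD of the centered matrix.

    Parameters
    ----------
    dataset
        K x N voxel dataset, K >= 2.
    L
        Retained components. Default is K (all), capped at the numerical
        rank M (<= K-1 after centering).
    """
    if dataset.n_subjects < 2:
        raise InsufficientDataError("need at least 2 subjects to fit eigenbrains")
    mean = dataset.data.mean(axis=0)
    centered = dataset.data - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > _RANK_RTOL * max(s[0], 1e-300)))
    if rank == 0:
        raise InsufficientDataError(
            "all images are identical: centered matrix has rank 0"
        )
    basis = vt[:rank].T.copy()
    s = s[:rank].copy()
    # sign fix: largest-magnitude loading of each eigenbrain positive
    flip = np.sign(basis[np.abs(basis).argmax(axis=0), np.arange(rank)])
    flip[flip == 0] = 1.0
    basis *= flip
    if L is None:
        L = min(dataset.n_subjects, rank)
    if not 1 <= L <= rank:
        raise TruncationError(f"L={L} outside the model rank 1..{rank}")
    return EigenbrainModel(
        mean=mean,
        basis=basis,
        singular_values=s,
        L=int(L),
        mask=dataset.mask,
        geometry=dataset.geometry,
    )


def project(rows, model: EigenbrainModel, L: int | None = None, labels=None) -> ScoreMatrix:
    """Map rows (or a VoxelDataset) to latent scores: S_L = (X - mean) W_L."""
    if isinstance(rows, VoxelDataset):
        if labels is None:
            labels = rows.labels
        rows = rows.data
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    if rows.shape[1] != model.n_voxels:
        raise ValueError(
            f"rows have {rows.shape[1]} voxels but the model expects {model.n_voxels}"
        )
    if L is None:
        L = model.L
    if not 1 <= L <= model.M:
        raise TruncationError(f"L={L} exceeds model rank M={model.M}")
    scores = (rows - model.mean) @ model.basis[:, :L]
    if labels is None:
        labels = np.zeros(rows.shape[0], dtype=object)
    return ScoreMatrix(scores=scores, labels=labels)


def reconstruct(scores, model: EigenbrainModel) -> np.ndarray:
    """Inverse transform: X_hat = S_L W_L^T + mean.

    W is orthonormal so the inverse of the projection is the transpose;
    the centering mean is re-added.
    """
    if isinstance(scores, ScoreMatrix):
        scores = scores.scores
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    width = scores.shape[1]
    if width > model.M:
        raise TruncationError(f"score width {width} exceeds model rank M={model.M}")
    return scores @ model.basis[:, :width].T + model.mean


def clip_nonnegative(rows: np.ndarray) -> np.ndarray:
    """Zero out negative voxels (radiotracer concentration cannot be < 0)."""
    return np.maximum(np.asarray(rows, dtype=np.float64), 0.0)


# ---------------------------------------------------------------------------
# model bundle serialization: JSON metadata + one .npz array container


def save_model(model: EigenbrainModel, directory, extra_metadata: dict | None = None,
               export_eigenbrains: int = 0) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "eigensynth-model-bundle",
        "version": 1,
        "shape": list(model.geometry.shape),
        "affine": model.geometry.affine.tolist(),
        "voxel_units": model.geometry.voxel_units,
        "L": model.L,
        "M": model.M,
        "n_voxels": model.n_voxels,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    np.savez(
        directory / "arrays.npz",
        mean=model.mean,
        basis=model.basis,
        singular_values=model.singular_values,
        mask=model.mask,
    )
    for comp in range(min(export_eigenbrains, model.M)):
        write_volume(
            model.eigenbrain_volume(comp),
            model.geometry,
            directory / f"eigenbrain_{comp:03d}.nii.gz",
        )
    return directory


def load_model(directory) -> EigenbrainModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    arrays = np.load(directory / "arrays.npz")
    geometry = VolumeGeometry(
        shape=tuple(meta["shape"]),
        affine=np.asarray(meta["affine"]),
        voxel_units=meta.get("voxel_units", "mm"),
    )
    return EigenbrainModel(
        mean=arrays["mean"],
        basis=arrays["basis"],
        singular_values=arrays["singular_values"],
        L=int(meta["L"]),
        mask=arrays["mask"].astype(bool),
        geometry=geometry,
    )
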