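"""Drawing new subjects: latent sampling plus eigenbrain reconstruction.

For the KDE estimator, each latent component's PDF is integrated to a
tabulated CDF and new coordinates are drawn by inverse-transform
sampling: uniform variates in [0, 1] are treated as CDF values and mapped
back to scores by linear interpolation on the tabulated grid. Components
use independent uniform streams, consistent with the estimator's
independence assumption.

For the MVN estimator the draw is a direct multivariate one
(mu + C z with C the Cholesky factor of the shrunk covariance):
per-coordinate CDF inversion would destroy exactly the cross-component
correlations the MVN exists to preserve.

Sampled score vectors are mapped back to voxel space through the
orthonormal eigenbrain basis, with the dataset mean re-added and optional
clipping of negative voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import cholesky

from .decomposition import (
    EigenbrainModel,
    ScoreMatrix,
    clip_nonnegative,
    fit_eigenbrains,
    project,
    reconstruct,
)
from .density import (
    KDEClassModel,
    KDEComponentModel,
    MVNClassModel,
    fit_kde_class,
    fit_mvn,
    kde_pdf,
)
from .io_imaging import VoxelDataset

__all__ = [
    "TabulatedCDF",
    "SynthesisSpec",
    "GenerativeModel",
    "ModelStateError",
    "tabulate_cdf",
    "sample_inverse_cdf",
    "sample_mvn",
    "sample_kde_class",
    "fit_generative_model",
    "synthesize",
    "synthesize_classes",
]

#: kernel-bandwidth multiples by which the CDF grid extends past the data
_CDF_TAIL = 6.0


class ModelStateError(RuntimeError):
    """Synthesis requested for a class with no fitted density."""


@dataclass
class TabulatedCDF:
    """Numeric (x, F(x)) table used for interpolation-based inversion."""

    grid: np.ndarray
    cdf: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64).ravel()
        self.cdf = np.asarray(self.cdf, dtype=np.float64).ravel()
        if self.grid.size != self.cdf.size or self.grid.size < 2:
            raise ValueError("grid and cdf must be equal-length vectors (>= 2)")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(self.cdf) < 0):
            raise ValueError("cdf must be nondecreasing")
        if self.cdf[0] > 1e-6 or self.cdf[-1] < 1 - 1e-6:
            raise ValueError("cdf must start at ~0 and end at ~1")


def tabulate_cdf(model: KDEComponentModel, grid_points: int = 4096) -> TabulatedCDF:
    """Cumulative trapezoidal integral of the component KDE.

    The grid spans [min(points) - 6h, max(points) + 6h] so the Gaussian
    tails are negligible outside it; the integral is renormalized so the
    final value is exactly 1.
    """
    lo = model.points.min() - _CDF_TAIL * model.bandwidth
    hi = model.points.max() + _CDF_TAIL * model.bandwidth
    grid = np.linspace(lo, hi, grid_points)
    pdf = kde_pdf(model, grid)
    cdf = cumulative_trapezoid(pdf, grid, initial=0.0)
    cdf /= cdf[-1]
    return TabulatedCDF(grid=grid, cdf=cdf)


def sample_inverse_cdf(cdf: TabulatedCDF, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-transform sampling against a tabulated CDF.

    Uniform draws are interpolated linearly on (cdf, grid); flat CDF
    regions (zero-density gaps) are collapsed to keep the interpolant
    single-valued, and u = 0 / u = 1 clamp to the grid ends.
    """
    u = rng.uniform(0.0, 1.0, size=n)
    # keep the first grid point of every run of equal cdf values
    values, first_idx = np.unique(cdf.cdf, return_index=True)
    return np.interp(u, values, cdf.grid[first_idx])


def sample_mvn(model: MVNClassModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. draws from N(mu, sigma) via the Cholesky factor of sigma."""
    try:
        chol = cholesky(model.sigma, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - shrinkage guarantees PD
        raise RuntimeError("covariance is not positive definite") from exc
    z = rng.standard_normal((n, model.L))
    return model.mu + z @ chol.T


def sample_kde_class(
    model: KDEClassModel, n: int, rng: np.random.Generator, grid_points: int = 4096
) -> np.ndarray:
    """n draws from the per-component KDE model (independent components)."""
    out = np.empty((n, model.L))
    for l, comp in enumerate(model.components):
        out[:, l] = sample_inverse_cdf(tabulate_cdf(comp, grid_points), n, rng)
    return out


@dataclass(frozen=True)
class SynthesisSpec:
    """What to synthesize: class, count, estimator, truncation and seed."""

    class_id: object
    n_samples: int
    estimator: str = "kde"
    L: int | None = None
    seed: int = 0
    clip_negative: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.estimator not in {"mvn", "kde"}:
            raise ValueError(f"estimator must be 'mvn' or 'kde', got {self.estimator!r}")


@dataclass
class GenerativeModel:
    """Eigenbrain basis plus one fitted latent density per class."""

    eigen: EigenbrainModel
    estimator: str
    densities: dict = field(default_factory=dict)
    scores: ScoreMatrix | None = None

    @property
    def L(self) -> int:
        return self.eigen.L

    def density_for(self, class_id):
        try:
            return self.densities[class_id]
        except KeyError:
            raise ModelStateError(
                f"no fitted {self.estimator} density for class {class_id!r}"
            ) from None


def fit_generative_model(
    dataset: VoxelDataset,
    estimator: str = "kde",
    L: int | None = None,
    force_alpha: float | None = None,
) -> GenerativeModel:
    """Fit eigenbrains on the whole dataset and a latent density per class."""
    if estimator not in {"mvn", "kde"}:
        raise ValueError(f"estimator must be 'mvn' or 'kde', got {estimator!r}")
    eigen = fit_eigenbrains(dataset, L=L)
    scores = project(dataset, eigen, L=eigen.L)
    densities = {}
    for class_id in dataset.classes:
        if estimator == "mvn":
            densities[class_id] = fit_mvn(scores, class_id, force_alpha=force_alpha)
        else:
            densities[class_id] = fit_kde_class(scores, class_id)
    return GenerativeModel(eigen=eigen, estimator=estimator, densities=densities,
                           scores=scores)


def synthesize(model: GenerativeModel, spec: SynthesisSpec) -> VoxelDataset:
    """Generate ``spec.n_samples`` synthetic images of ``spec.class_id``.

    Deterministic given the spec (same seed, estimator, L and count give a
    bit-identical dataset). Provenance is encoded in the subject ids.
    """
    if spec.estimator != model.estimator:
        raise ModelStateError(
            f"model was fitted with estimator {model.estimator!r}, "
            f"spec requests {spec.estimator!r}"
        )
    L = model.L if spec.L is None else spec.L
    if L != model.L:
        raise ModelStateError(
            f"model densities were fitted at L={model.L}; refit to synthesize at L={L}"
        )
    density = model.density_for(spec.class_id)
    rng = np.random.default_rng(spec.seed)
    if model.estimator == "mvn":
        latent = sample_mvn(density, spec.n_samples, rng)
    else:
        latent = sample_kde_class(density, spec.n_samples, rng)
    rows = reconstruct(latent, model.eigen)
    if spec.clip_negative:
        rows = clip_nonnegative(rows)
    tag = f"{spec.class_id}-{spec.estimator}-L{L}-s{spec.seed}"
    return VoxelDataset(
        data=rows,
        labels=np.asarray([spec.class_id] * spec.n_samples, dtype=object),
        mask=model.eigen.mask,
        geometry=model.eigen.geometry,
        subject_ids=np.asarray(
            [f"syn-{tag}-{i:04d}" for i in range(spec.n_samples)], dtype=object
        ),
    )


def synthesize_classes(
    model: GenerativeModel,
    n_per_class: int,
    seed: int,
    classes=None,
    clip_negative: bool = False,
) -> VoxelDataset:
    """Synthesize a balanced multi-class dataset (one sub-seed per class)."""
    if classes is None:
        classes = list(model.densities)
    parts = []
    for offset, class_id in enumerate(classes):
        spec = SynthesisSpec(
            class_id=class_id,
            n_samples=n_per_class,
            estimator=model.estimator,
            L=model.L,
            seed=(seed * 1000 + offset) % (2**31),
            clip_negative=clip_negative,
        )
        parts.append(synthesize(model, spec))
    first = parts[0]
    return VoxelDataset(
        data=np.vstack([p.data for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        mask=first.mask,
        geometry=first.geometry,
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
    )
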