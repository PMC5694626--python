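"""Phantom generator: small 3D brain-like datasets with known structure.

Every downstream module is exercised on these phantoms, so they emulate
the statistical structure the synthesis model assumes about co-registered
nuclear-imaging stacks: an ellipsoidal "brain" with positive uptake on a
zero background, class-specific regional intensity offsets (spherical
lesions/deficits), a low-dimensional space of smooth inter-subject
variation modes, voxel noise, and overall spatial smoothness.

Each subject volume is built as::

    base template + class-effect spheres
        + sum_m  c_m * mode_m        (c_m ~ N(0, latent_sd_m))
        + noise_sd * white noise

then Gaussian-smoothed (sigma = FWHM / 2.3548) and clipped at zero. The
ground truth (noise-free class templates, spatial modes, latent draws) is
returned alongside, enabling parameter-recovery tests.

Two presets mirror the shape of real cohorts: a three-class
normal / intermediate / strong-deficit dataset with the intermediate
class's effect halfway between the extremes (an FDG-PET-like progressive
disorder with overlapping classes), and a two-class dataset whose classes
differ in two small bright bilateral "striatum-like" foci with
class-dependent amplitude and asymmetry (a DaTSCAN-like scenario).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_imaging import VolumeGeometry, VoxelDataset, flatten

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "phantom_adni_like",
    "phantom_ppmi_like",
    "ADNI_LIKE_SPEC",
    "PPMI_LIKE_SPEC",
]

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # sigma = FWHM / (2 sqrt(2 ln 2))


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a phantom cohort; deterministic given ``seed``."""

    shape: tuple[int, int, int] = (24, 24, 24)
    class_names: tuple = ("A", "B")
    n_per_class: tuple = (20, 20)
    #: per class: list of (center voxel, radius in voxels, amplitude) spheres
    class_effects: dict = field(default_factory=dict)
    latent_dim: int = 4
    latent_sd: tuple = (0.4, 0.3, 0.2, 0.1)
    #: sd of a per-subject variation mode aligned with the mean class-effect
    #: pattern (all classes share it): a "disease spectrum" axis that makes
    #: class overlap irreducible, as in real progressive disorders
    pattern_jitter_sd: float = 0.0
    noise_sd: float = 0.2
    smoothing_fwhm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_names) != len(self.n_per_class):
            raise ValueError("class_names and n_per_class must align")
        if any(n < 2 for n in self.n_per_class):
            raise ValueError("every class needs at least 2 subjects")
        if len(self.latent_sd) != self.latent_dim:
            raise ValueError("latent_sd must have latent_dim entries")
        if any(sd < 0 for sd in self.latent_sd) or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        half = min(self.shape) / 2
        for cls, spheres in self.class_effects.items():
            for center, radius, amplitude in spheres:
                if not np.isfinite(amplitude):
                    raise ValueError(f"class {cls}: non-finite amplitude")
                if radius >= half:
                    raise ValueError(f"class {cls}: sphere radius {radius} too large")


@dataclass
class PhantomGroundTruth:
    """What the generator actually used, for recovery tests."""

    class_templates: dict          # class -> noise-free flattened mean image
    modes: np.ndarray              # latent_dim x N spatial variation modes
    latent_draws: np.ndarray       # K x latent_dim subject coefficients
    spec: PhantomSpec


def _ellipsoid(shape: tuple[int, int, int], scale: float = 0.42) -> np.ndarray:
    axes = [np.arange(s, dtype=float) - (s - 1) / 2 for s in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    semi = [scale * s for s in shape]
    return (zz / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (xx / semi[2]) ** 2 <= 1.0


def _sphere(shape: tuple[int, int, int], center, radius: float) -> np.ndarray:
    axes = [np.arange(s, dtype=float) for s in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return d2 <= radius ** 2


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelDataset, PhantomGroundTruth]:
    """Generate the cohort described by ``spec`` plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    sigma = spec.smoothing_fwhm * FWHM_TO_SIGMA

    brain = _ellipsoid(shape)
    template = brain.astype(float)  # uniform unit uptake inside the brain
    mask = brain.copy()
    n_voxels = int(mask.sum())

    # smooth spatial variation modes, unit RMS inside the brain, so that
    # latent_sd is expressed directly in intensity units
    modes = np.empty((spec.latent_dim, n_voxels))
    for m in range(spec.latent_dim):
        field3d = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
        field3d *= brain
        rms = np.sqrt(np.mean(field3d[mask] ** 2))
        modes[m] = field3d[mask] / rms

    class_volumes = {}
    class_templates = {}
    effect_fields = []
    for cls in spec.class_names:
        vol = template.copy()
        effect = np.zeros(shape)
        for center, radius, amplitude in spec.class_effects.get(cls, []):
            effect += amplitude * (_sphere(shape, center, radius) & brain)
        vol += effect
        effect_fields.append(effect)
        class_volumes[cls] = vol
        class_templates[cls] = flatten(
            np.clip(gaussian_filter(vol, sigma=sigma), 0.0, None), mask
        )

    mode_sds = list(spec.latent_sd)
    if spec.pattern_jitter_sd > 0:
        pattern = np.mean(effect_fields, axis=0)[mask]
        rms = np.sqrt(np.mean(pattern ** 2))
        if rms > 0:
            modes = np.vstack([modes, pattern / rms])
            mode_sds.append(spec.pattern_jitter_sd)

    n_modes = modes.shape[0]
    total = int(sum(spec.n_per_class))
    data = np.empty((total, n_voxels))
    labels = np.empty(total, dtype=object)
    latent_draws = np.empty((total, n_modes))
    subject_ids = np.empty(total, dtype=object)
    row = 0
    for cls, n_cls in zip(spec.class_names, spec.n_per_class):
        for _ in range(int(n_cls)):
            coeff = rng.standard_normal(n_modes) * np.asarray(mode_sds)
            vol = class_volumes[cls].copy()
            vol[mask] += modes.T @ coeff
            if spec.noise_sd > 0:
                vol += spec.noise_sd * rng.standard_normal(shape)
            vol = np.clip(gaussian_filter(vol, sigma=sigma), 0.0, None)
            data[row] = flatten(vol, mask)
            labels[row] = cls
            latent_draws[row] = coeff
            subject_ids[row] = f"phantom-{cls}-{row:04d}"
            row += 1

    geometry = VolumeGeometry(shape=shape, affine=np.diag([2.0, 2.0, 2.0, 1.0]))
    dataset = VoxelDataset(
        data=data, labels=labels, mask=mask, geometry=geometry, subject_ids=subject_ids
    )
    truth = PhantomGroundTruth(
        class_templates=class_templates,
        modes=modes,
        latent_draws=latent_draws,
        spec=spec,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# presets
#
# Amplitudes, variability and noise were calibrated once so the cohorts show
# the qualitative structure of the real populations they emulate: the
# three-class preset has a clearly separable strong-deficit class and an
# intermediate class that overlaps the controls (its effect is exactly half
# the strong effect); the two-class preset is strongly separable through two
# focal high-uptake regions with reduced, asymmetric uptake in the disease
# class.

_AD_SPHERES = [
    ((8, 9, 13), 3.0, -0.42),    # "temporo-parietal" deficit, left
    ((15, 9, 13), 3.0, -0.42),   # right
    ((11, 15, 11), 2.5, -0.30),  # "posterior cingulate / precuneus" deficit
]

ADNI_LIKE_SPEC = PhantomSpec(
    shape=(24, 24, 24),
    class_names=("NOR", "MCI", "AD"),
    n_per_class=(60, 60, 60),
    class_effects={
        "NOR": [],
        # intermediate class: effect amplitude halfway between NOR and AD
        "MCI": [(c, r, a / 2) for c, r, a in _AD_SPHERES],
        "AD": list(_AD_SPHERES),
    },
    latent_dim=8,
    latent_sd=(0.45, 0.35, 0.30, 0.25, 0.20, 0.15, 0.12, 0.10),
    pattern_jitter_sd=0.04,
    noise_sd=0.25,
    smoothing_fwhm=2.0,
    seed=2017,
)

PPMI_LIKE_SPEC = PhantomSpec(
    shape=(24, 24, 24),
    class_names=("NOR", "PD"),
    n_per_class=(60, 60),
    class_effects={
        # bright bilateral "striatum-like" foci; the disease class shows a
        # reduced and left/right-asymmetric signal
        "NOR": [((9, 12, 12), 2.5, 2.0), ((14, 12, 12), 2.5, 2.0)],
        "PD": [((9, 12, 12), 2.5, 1.1), ((14, 12, 12), 2.5, 0.8)],
    },
    latent_dim=6,
    latent_sd=(0.40, 0.30, 0.25, 0.20, 0.15, 0.10),
    pattern_jitter_sd=0.066,
    noise_sd=0.20,
    smoothing_fwhm=2.0,
    seed=2017,
)


def phantom_adni_like(seed: int | None = None, n_per_class: tuple | None = None):
    """Three overlapping classes (NOR / intermediate MCI / strong AD)."""
    spec = ADNI_LIKE_SPEC
    if seed is not None or n_per_class is not None:
        spec = PhantomSpec(
            **{
                **spec.__dict__,
                **({"seed": seed} if seed is not None else {}),
                **({"n_per_class": tuple(n_per_class)} if n_per_class is not None else {}),
            }
        )
    return generate_phantom(spec)


def phantom_ppmi_like(seed: int | None = None, n_per_class: tuple | None = None):
    """Two classes differing in focal bright regions (NOR / PD)."""
    spec = PPMI_LIKE_SPEC
    if seed is not None or n_per_class is not None:
        spec = PhantomSpec(
            **{
                **spec.__dict__,
                **({"seed": seed} if seed is not None else {}),
                **({"n_per_class": tuple(n_per_class)} if n_per_class is not None else {}),
            }
        )
    return generate_phantom(spec)
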