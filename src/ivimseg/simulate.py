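"""Synthetic IVIM data: Rician-noise curves and a two-region phantom volume.

The simulation design mirrors a standard low-perfusion benchmarking setup:
a fixed molecular-diffusion coefficient (D = 1.0e-3 mm^2/s), a grid of
perfusion parameter combinations (f from 0.02 to 0.50 in steps of 0.02;
D* from 2.0e-3 to 60e-3 mm^2/s in steps of 2.0e-3), 18 b-values between 0 and
500 s/mm^2, Rician noise at SNR levels 10/20/40 (SNR = S(0) / noise sigma),
and 1000 replicates per grid cell.

The phantom generator builds a small 4D volume containing two ellipsoidal
"femoral heads" — one perfused (control) and one non-perfused (ischemic) —
in a signal-free background, emulating a bilateral-hip acquisition for
exercising the voxelwise mapping pipeline end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import InputDomainError, IVIMParams, SignalCurve, ivim_signal

__all__ = [
    "ConfigError",
    "DEFAULT_BVALUES",
    "SimulationSpec",
    "PhantomSpec",
    "add_rician_noise",
    "generate_replicates",
    "generate_replicate_matrix",
    "generate_phantom",
    "save_phantom_nifti",
]


class ConfigError(ValueError):
    """A configuration value is invalid or inconsistent."""


#: Default acquisition scheme: 0 and 20..100 in steps of 10, then 150..500 in
#: steps of 50 (s/mm^2).
DEFAULT_BVALUES = np.array(
    [0, 20, 30, 40, 50, 60, 70, 80, 90, 100, 150, 200, 250, 300, 350, 400, 450, 500],
    dtype=float,
)


def _default_f_grid() -> np.ndarray:
    return np.round(np.arange(0.02, 0.50 + 1e-9, 0.02), 10)


def _default_dstar_grid() -> np.ndarray:
    return np.round(np.arange(2.0e-3, 60e-3 + 1e-9, 2.0e-3), 10)


@dataclass
class SimulationSpec:
    """Parameter grid and noise settings for a replicate simulation study."""

    D_fixed: float = 1.0e-3
    f_grid: np.ndarray = field(default_factory=_default_f_grid)
    Dstar_grid: np.ndarray = field(default_factory=_default_dstar_grid)
    bvalues: np.ndarray = field(default_factory=lambda: DEFAULT_BVALUES.copy())
    snr_levels: tuple = (10.0, 20.0, 40.0)
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.f_grid = np.asarray(self.f_grid, dtype=float)
        self.Dstar_grid = np.asarray(self.Dstar_grid, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if self.D_fixed <= 0:
            raise ConfigError("D_fixed must be positive")
        if np.any(self.f_grid <= 0) or np.any(self.f_grid > 1):
            raise ConfigError("f_grid values must lie in (0, 1]")
        if np.any(self.Dstar_grid <= 0):
            raise ConfigError("Dstar_grid values must be positive")
        if any(s <= 0 for s in self.snr_levels):
            raise ConfigError("snr_levels must be positive")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        # delegate b-value checks to the curve invariants
        SignalCurve(self.bvalues, np.ones_like(self.bvalues))


@dataclass
class PhantomSpec:
    """Geometry and contrast of the synthetic two-femoral-head phantom.

    ``shape`` is the 3D voxel grid; the two ellipsoidal regions are placed at
    configurable centers with configurable semi-axes (in voxels) and must be
    disjoint and non-empty.  ``snr`` may be ``numpy.inf`` for a noiseless
    phantom.
    """

    shape: tuple = (24, 12, 5)
    control_params: IVIMParams = field(
        default_factory=lambda: IVIMParams(D=1.0e-3, Dstar=30e-3, f=0.12)
    )
    ischemic_params: IVIMParams = field(
        default_factory=lambda: IVIMParams(D=1.6e-3, Dstar=5e-3, f=0.03)
    )
    snr: float = 40.0
    seed: int = 0
    bvalues: np.ndarray = field(default_factory=lambda: DEFAULT_BVALUES.copy())
    control_center: tuple | None = None
    ischemic_center: tuple | None = None
    semiaxes: tuple | None = None

    def __post_init__(self) -> None:
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ConfigError("shape must be three positive dimensions")
        if self.snr <= 0:
            raise ConfigError("snr must be positive")
        nx, ny, nz = self.shape
        if self.control_center is None:
            self.control_center = (nx * 0.25, ny * 0.5, nz * 0.5)
        if self.ischemic_center is None:
            self.ischemic_center = (nx * 0.75, ny * 0.5, nz * 0.5)
        if self.semiaxes is None:
            # two "femoral heads" separated by background
            self.semiaxes = (nx * 0.16, ny * 0.3, max(nz * 0.35, 0.6))


def add_rician_noise(signal, S0: float, snr: float, rng) -> np.ndarray:
    """Corrupt a magnitude signal with Rician noise at a given SNR.

    The noise is realized the standard MRI way, as the magnitude of a complex
    Gaussian perturbation: ``sqrt((S + n1)^2 + n2^2)`` with ``n1``, ``n2``
    independent zero-mean Gaussians of standard deviation ``S0 / snr``.
    ``snr = numpy.inf`` returns the signal unchanged.

    Parameters
    ----------
    signal : array_like
        Noiseless magnitude signal (non-negative).
    S0 : float
        Reference b=0 intensity defining the SNR.
    snr : float
        Ratio of S0 to the noise standard deviation; must be > 0.
    rng : numpy.random.Generator
    """
    if snr <= 0:
        raise InputDomainError(f"snr must be positive, got {snr}")
    s = np.asarray(signal, dtype=float)
    if np.isinf(snr):
        return s.copy()
    sigma = S0 / snr
    n1 = rng.normal(0.0, sigma, size=s.shape)
    n2 = rng.normal(0.0, sigma, size=s.shape)
    return np.sqrt((s + n1) ** 2 + n2**2)


def generate_replicate_matrix(
    params: IVIMParams, bvalues, snr: float, n_reps: int, rng
) -> np.ndarray:
    """Noisy replicate curves as an (n_reps, n_b) array with S0 = 1."""
    b = np.asarray(bvalues, dtype=float)
    clean = ivim_signal(params, b, S0=1.0)
    if np.isinf(snr):
        return np.tile(clean, (n_reps, 1))
    out = np.empty((n_reps, b.size))
    sigma = 1.0 / snr
    n1 = rng.normal(0.0, sigma, size=out.shape)
    n2 = rng.normal(0.0, sigma, size=out.shape)
    np.sqrt((clean[None, :] + n1) ** 2 + n2**2, out=out)
    return out


def generate_replicates(
    params: IVIMParams, bvalues, snr: float, n_reps: int, rng
) -> list[SignalCurve]:
    """Generate ``n_reps`` independent Rician-noise signal curves (S0 = 1)."""
    mat = generate_replicate_matrix(params, bvalues, snr, n_reps, rng)
    b = np.asarray(bvalues, dtype=float)
    return [SignalCurve(b, mat[i]) for i in range(n_reps)]


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Build the two-region 4D phantom volume.

    Returns
    -------
    data : ndarray, shape ``spec.shape + (len(bvalues),)``
        One 3D volume per b-value.  Region voxels follow the region's IVIM
        parameters (S0 = 1) with Rician noise; background voxels carry the
        pure noise floor.
    masks : dict
        ``{"control": 3D bool, "ischemic": 3D bool}``.
    """
    control = _ellipsoid_mask(spec.shape, spec.control_center, spec.semiaxes)
    ischemic = _ellipsoid_mask(spec.shape, spec.ischemic_center, spec.semiaxes)
    if not control.any() or not ischemic.any():
        raise ConfigError("phantom regions are empty; enlarge shape or semiaxes")
    if (control & ischemic).any():
        raise ConfigError("phantom regions overlap; move centers apart")

    b = spec.bvalues
    rng = np.random.default_rng(spec.seed)
    clean = np.zeros(spec.shape + (b.size,))
    clean[control] = ivim_signal(spec.control_params, b, S0=1.0)
    clean[ischemic] = ivim_signal(spec.ischemic_params, b, S0=1.0)
    data = add_rician_noise(clean, S0=1.0, snr=spec.snr, rng=rng)
    return data, {"control": control, "ischemic": ischemic}


def save_phantom_nifti(data, masks, bvalues, outdir, prefix: str = "phantom"):
    """Write the phantom as NIfTI volumes plus an FSL-style .bval sidecar.

    Produces ``<prefix>.nii.gz`` (4D, 4th axis = b-value index), one mask
    NIfTI per region, and ``<prefix>.bval`` containing one whitespace-
    separated row of b-values.  Returns the path of the 4D image.
    """
    import os

    import nibabel as nib

    affine = np.eye(4)
    os.makedirs(outdir, exist_ok=True)
    img_path = os.path.join(outdir, f"{prefix}.nii.gz")
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), img_path)
    for name, mask in masks.items():
        nib.save(
            nib.Nifti1Image(mask.astype(np.uint8), affine),
            os.path.join(outdir, f"{prefix}_{name}_mask.nii.gz"),
        )
    with open(os.path.join(outdir, f"{prefix}.bval"), "w") as fh:
        fh.write(" ".join(f"{v:g}" for v in np.asarray(bvalues).ravel()) + "\n")
    return img_path
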