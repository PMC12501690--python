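"""Voxelwise IVIM parameter mapping and paired ROI comparison.

Reads 4D diffusion-weighted volumes (one 3D volume per b-value, NIfTI with an
FSL-style ``.bval`` sidecar), fits every in-mask voxel with one of the four
segmented methods, and supports ROI median extraction plus paired
ischemic-vs-control statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fitting import FitResult, InsufficientDataError, fit_curve
from .model import InputDomainError, SignalCurve

__all__ = [
    "DiffusionVolume",
    "ParameterMaps",
    "PairedComparison",
    "fit_image",
    "roi_median",
    "paired_compare",
    "MAP_PARAMS",
]

MAP_PARAMS = ("D", "Dstar", "f", "flux")

#: Value marking voxels that were outside the mask or could not be fitted.
SENTINEL = np.nan


@dataclass
class DiffusionVolume:
    """A 4D diffusion acquisition: (x, y, z, b-index) data plus b-values.

    On construction the b-value axis is sorted ascending and the data
    re-indexed to match, so downstream per-voxel curves satisfy the
    signal-curve invariants regardless of on-disk ordering.
    """

    data: np.ndarray
    bvalues: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        if self.data.ndim != 4:
            raise InputDomainError("data must be 4D (x, y, z, b)")
        if self.data.shape[3] != self.bvalues.size:
            raise InputDomainError(
                f"4th axis ({self.data.shape[3]}) does not match "
                f"number of b-values ({self.bvalues.size})"
            )
        if 0.0 not in self.bvalues:
            raise InputDomainError("acquisition must include b = 0")
        order = np.argsort(self.bvalues, kind="stable")
        if not np.array_equal(order, np.arange(order.size)):
            self.bvalues = self.bvalues[order]
            self.data = self.data[..., order]

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    @classmethod
    def from_nifti(cls, image_path, bval_path) -> "DiffusionVolume":
        """Load a 4D NIfTI plus its whitespace-separated .bval sidecar."""
        import nibabel as nib

        img = nib.load(str(image_path))
        with open(bval_path) as fh:
            bvals = np.array(fh.read().split(), dtype=float)
        return cls(data=np.asanyarray(img.dataobj), bvalues=bvals, affine=img.affine)


@dataclass
class ParameterMaps:
    """Voxelwise parameter maps produced by :func:`fit_image`.

    ``maps`` holds one 3D float array per parameter (D, Dstar, f, flux);
    voxels outside the mask or with failed fits carry NaN.  ``converged``
    marks voxels whose fit converged.
    """

    maps: dict
    converged: np.ndarray
    method: str
    options: dict = field(default_factory=dict)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def to_nifti(self, outdir, prefix: str = "ivim"):
        """Write one NIfTI per parameter map plus the convergence mask."""
        import os

        import nibabel as nib

        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name, arr in self.maps.items():
            p = os.path.join(outdir, f"{prefix}_{self.method}_{name}.nii.gz")
            nib.save(nib.Nifti1Image(arr.astype(np.float32), self.affine), p)
            paths[name] = p
        p = os.path.join(outdir, f"{prefix}_{self.method}_converged.nii.gz")
        nib.save(nib.Nifti1Image(self.converged.astype(np.uint8), self.affine), p)
        paths["converged"] = p
        return paths


def default_mask(volume: DiffusionVolume, fraction: float = 0.05) -> np.ndarray:
    """Foreground mask: b=0 intensity above ``fraction`` of its 99th percentile."""
    b0 = volume.data[..., 0]
    thresh = fraction * np.percentile(b0, 99)
    return b0 > thresh


def fit_image(
    volume: DiffusionVolume,
    method: str,
    options: dict | None = None,
    mask: np.ndarray | None = None,
) -> ParameterMaps:
    """Fit every in-mask voxel's decay curve with the chosen method.

    ``options`` may carry ``b_t`` (required for S/OS/AS) and
    ``mask_fraction`` for the default foreground mask.  Per-voxel failures
    (all-zero signal, too few usable points, non-convergence) are recorded in
    the convergence mask; the call never aborts on a degenerate voxel.  The
    result is independent of voxel iteration order: each voxel's fit depends
    only on its own curve.
    """
    options = dict(options or {})
    b_t = options.get("b_t")
    if mask is None:
        mask = default_mask(volume, options.get("mask_fraction", 0.05))
    if mask.shape != volume.shape:
        raise InputDomainError("mask shape does not match volume spatial shape")

    shape = volume.shape
    maps = {p: np.full(shape, SENTINEL) for p in MAP_PARAMS}
    converged = np.zeros(shape, dtype=bool)
    b = volume.bvalues

    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        sig = volume.data[idx]
        try:
            curve = SignalCurve.from_measurements(b, sig)
            res: FitResult = fit_curve(curve, method, b_t)
        except (InputDomainError, InsufficientDataError):
            continue
        for name in MAP_PARAMS:
            maps[name][idx] = res.estimates[name]
        converged[idx] = res.converged

    return ParameterMaps(
        maps=maps, converged=converged, method=method, options=options, affine=volume.affine
    )


def roi_median(maps: ParameterMaps, roi_mask: np.ndarray) -> dict:
    """Median of each parameter over converged, in-ROI voxels.

    Sentinel (non-fitted) voxels are excluded before taking the median; an
    ROI with no usable voxels raises :class:`InputDomainError`.
    """
    if roi_mask.shape != maps.converged.shape:
        raise InputDomainError("ROI mask shape does not match maps")
    usable = roi_mask & maps.converged
    out = {}
    for name, arr in maps.maps.items():
        vals = arr[usable]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise InputDomainError(f"ROI contains no usable voxels for {name}")
        out[name] = float(np.median(vals))
        out[f"{name}_mean"] = float(np.mean(vals))  # diagnostic alongside the median
    out["n_voxels"] = int(usable.sum())
    return out


@dataclass(frozen=True)
class PairedComparison:
    mean_diff: float
    sd_diff: float
    t: float
    p: float
    n: int
    message: str = ""


def paired_compare(medians_a, medians_b) -> PairedComparison:
    """Two-sided paired t-test on per-subject differences (a - b).

    Differences use the sample (N-1) standard deviation.  A zero-variance
    difference vector is degenerate for the t-test: p is reported as 1 when
    the mean difference is also 0, and 0 otherwise, with an explanatory
    message.
    """
    a = np.asarray(medians_a, dtype=float)
    b = np.asarray(medians_b, dtype=float)
    if a.shape != b.shape:
        raise InputDomainError("paired vectors must have equal length")
    if a.size < 2:
        raise InputDomainError("need at least 2 subjects for a paired test")
    diff = a - b
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedComparison(0.0, 0.0, 0.0, 1.0, a.size, "zero-variance, zero-mean differences")
        t = np.inf if mean > 0 else -np.inf
        return PairedComparison(mean, 0.0, t, 0.0, a.size, "zero-variance differences")
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(mean, sd, float(t), float(p), a.size)
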