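"""Bi-exponential IVIM signal model and core data types.

The intravoxel incoherent motion (IVIM) model describes the diffusion-weighted
MRI signal of a voxel as a mixture of two compartments: slow molecular
diffusion in tissue (coefficient ``D``) and fast pseudo-diffusion attributed to
capillary microcirculation (coefficient ``D*``, signal fraction ``f``)::

    S(b) = S(0) * [ f * exp(-b (D + D*)) + (1 - f) * exp(-b D) ]

Note the convention used throughout this package: the perfusion compartment
decays with ``D + D*``, so the apparent diffusion coefficient at ``b -> 0`` is
exactly ``D + f D*``.  Every fitter in :mod:`ivimseg.fitting` uses the same
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InputDomainError",
    "IVIMParams",
    "SignalCurve",
    "ivim_signal",
    "apparent_diffusion_at_origin",
]


class InputDomainError(ValueError):
    """An input violates the physical/mathematical domain of an operation."""


@dataclass(frozen=True)
class IVIMParams:
    """IVIM parameter triple.

    Parameters
    ----------
    D : float
        Molecular-diffusion coefficient, mm^2/s.  Must be >= 0.
    Dstar : float
        Pseudo-diffusion coefficient, mm^2/s.  Must be >= 0.
    f : float
        Pseudo-diffusion (perfusion) signal fraction, in [0, 1].

    The pseudo-diffusion flux ``f * Dstar`` is exposed as the derived
    property :attr:`flux`; it is always recomputed, never stored.
    """

    D: float
    Dstar: float
    f: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise InputDomainError(f"f must be in [0, 1], got {self.f}")
        if self.D < 0:
            raise InputDomainError(f"D must be >= 0, got {self.D}")
        if self.Dstar < 0:
            raise InputDomainError(f"Dstar must be >= 0, got {self.Dstar}")

    @property
    def flux(self) -> float:
        """Pseudo-diffusion flux f * D*, mm^2/s."""
        return self.f * self.Dstar


@dataclass(frozen=True)
class SignalCurve:
    """A single diffusion signal decay curve.

    Invariants: b-values strictly increasing starting at 0, at least 4 points
    (the minimum for any two-stage fit), and a positive b=0 signal.  Use
    :meth:`from_measurements` to build a curve from raw acquisitions with
    possibly duplicated or unsorted b-values (duplicates are averaged).
    """

    bvalues: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "signal", s)
        if b.ndim != 1 or s.ndim != 1 or b.size != s.size:
            raise InputDomainError("bvalues and signal must be 1D of equal length")
        if b.size < 4:
            raise InputDomainError(f"need at least 4 b-values, got {b.size}")
        if b[0] != 0.0:
            raise InputDomainError("first b-value must be 0")
        if np.any(np.diff(b) <= 0):
            raise InputDomainError("b-values must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise InputDomainError("signal contains non-finite values")
        if s[0] <= 0:
            raise InputDomainError("S(0) must be positive")

    @property
    def S0(self) -> float:
        """Measured signal at b = 0."""
        return float(self.signal[0])

    @property
    def n(self) -> int:
        return int(self.bvalues.size)

    @classmethod
    def from_measurements(cls, bvalues, signal) -> "SignalCurve":
        """Build a curve from raw (b, signal) pairs.

        Sorts by b-value and averages the signals of duplicated b-values, so
        repeated acquisitions at the same weighting collapse to one point.
        """
        b = np.asarray(bvalues, dtype=float)
        s = np.asarray(signal, dtype=float)
        if b.shape != s.shape:
            raise InputDomainError("bvalues and signal must have equal length")
        ub, inv = np.unique(b, return_inverse=True)
        mean_s = np.bincount(inv, weights=s) / np.bincount(inv)
        return cls(bvalues=ub, signal=mean_s)


def ivim_signal(params: IVIMParams, bvalues, S0: float = 1.0) -> np.ndarray:
    """Evaluate the bi-exponential IVIM forward model.

    Returns ``S0 * [f exp(-b (D + D*)) + (1 - f) exp(-b D)]`` elementwise.

    Parameters
    ----------
    params : IVIMParams
    bvalues : array_like
        Non-negative diffusion weightings, s/mm^2.
    S0 : float
        Signal at b = 0; must be positive.
    """
    b = np.asarray(bvalues, dtype=float)
    if np.any(b < 0):
        raise InputDomainError("b-values must be non-negative")
    if S0 <= 0:
        raise InputDomainError(f"S0 must be positive, got {S0}")
    perf = params.f * np.exp(-b * (params.D + params.Dstar))
    diff = (1.0 - params.f) * np.exp(-b * params.D)
    return S0 * (perf + diff)


def apparent_diffusion_at_origin(params: IVIMParams) -> float:
    """ADC of the mono-exponential tangent at b = 0.

    Equals ``D + f * D*``: the negative slope of ``log(S/S0)`` at the origin,
    i.e. the decay constant a mono-exponential fit would see in the limit of
    vanishing diffusion weighting.
    """
    return params.D + params.f * params.Dstar
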