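"""Segmented IVIM parameter-extraction methods: S, OS, AS, and opAS.

All four methods are two-stage ("segmented") fits built on the assumption that
pseudo-diffusion is negligible above some b-threshold ``b_t``:

* **S** (segmented): D from a log-linear mono-exponential fit over b >= b_t;
  then (f, D*) by nonlinear least squares of the full bi-exponential model
  over all b-values with D and S(0) fixed.
* **OS** (oversegmented): D and the intercept ``S_int`` from the same
  mono-exponential fit; f = 1 - S_int/S(0) directly; D* is the sole remaining
  nonlinear parameter.
* **AS** (analytical segmented): with D in hand, the signal is transformed to
  the pseudo-diffusion residual curve ``f~(b) = 1 - [S(b)/S(0)] e^{bD}``,
  which for exact D equals ``f (1 - e^{-b D*})``.  f~ is fitted with the
  three-parameter model ``f0 (1 - e^{-b D*}) + eps``, where ``eps`` absorbs
  error in the measured S(0); the asymptote f0 is the f estimate.
* **opAS** (optimized AS): threshold-free.  The mono-exponential estimate
  ``D~(b_t)`` is computed for a whole series of thresholds and fitted with
  ``D~(b_t) = ADC - P (1 - e^{-b_t D*_tmp})`` (P standing for the product
  f0 D*); the b_t -> infinity limit ``D = ADC - P`` removes the threshold
  dependence, after which f0 and D* are estimated exactly as in AS.

Two numerical choices matter and are applied uniformly:

* **Identifiability floor on D*.**  Below ``1/b_max`` the saturation term
  ``1 - e^{-b D*}`` is in its linear regime over the whole acquisition, so
  only the product f0*D* is determined and the optimizer would park at an
  arbitrary point of a flat valley.  Every nonlinear stage therefore bounds
  D* (and the trend stage D*_tmp) at the reciprocal of the largest sampled
  b (respectively b_t).
* **Raw vs. physical estimates.**  The fraction is *fitted* in [-1, 1]: with
  truth near f = 0, a [0, 1]-constrained estimator can only err upward and
  its replicate mean is biased.  ``FitResult.estimates`` carries the raw
  estimator values (the surface to benchmark); ``FitResult.params`` carries
  values clipped to the physical ranges, with any clip noted in ``message``.

Optimizer failures fall back to the initial values with ``converged=False``
so that voxelwise map fitting never aborts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares

from .model import InputDomainError, IVIMParams, SignalCurve, ivim_signal
from .simulate import ConfigError

__all__ = [
    "InsufficientDataError",
    "MonoExpFit",
    "PseudoDiffusionCurve",
    "FitResult",
    "fit_monoexp",
    "fit_S",
    "fit_OS",
    "compute_f_tilde",
    "fit_AS",
    "estimate_D_opAS",
    "fit_opAS",
    "fit_curve",
    "fit_batch",
    "default_bt_series",
    "METHODS",
]

METHODS = ("S", "OS", "AS", "opAS")

# Bounds shared by the nonlinear stages (mm^2/s where dimensional).  The
# fraction is fitted in [-1, 1]; see module docstring.
F_FIT_BOUNDS = (-1.0, 1.0)
DSTAR_MAX = 0.5
EPS_BOUNDS = (-0.5, 0.5)
ADC_BOUNDS = (1e-6, 1e-1)
P_BOUNDS = (0.0, 1e-1)


class InsufficientDataError(ValueError):
    """Too few usable data points for the requested fit."""


@dataclass(frozen=True)
class MonoExpFit:
    """Result of the log-linear mono-exponential tail fit.

    ``D_tilde`` is the raw slope estimate (may be negative under noise; it is
    clipped only where a non-negative D is mathematically required),
    ``S_int`` the fitted y-intercept, ``b_t`` the threshold used.
    """

    D_tilde: float
    S_int: float
    b_t: float


@dataclass(frozen=True)
class PseudoDiffusionCurve:
    """The transformed residual curve f~(b); f~(0) is 0 by construction."""

    bvalues: np.ndarray
    f_tilde: np.ndarray


@dataclass
class FitResult:
    """Uniform result of any of the four fitters.

    ``params`` holds physically clipped values; ``estimates`` the raw
    estimator outputs {D, Dstar, f, flux} used for benchmarking.
    """

    method: str
    params: IVIMParams
    estimates: dict = field(default_factory=dict)
    intermediates: dict = field(default_factory=dict)
    converged: bool = True
    message: str = ""


class OpASDEstimate(NamedTuple):
    D: float
    ADC: float
    fD_product: float
    Dstar_tmp: float
    converged: bool


def _dstar_floor(bmax: float) -> float:
    """Smallest D* whose saturation is resolvable within the sampled range."""
    return 1.0 / bmax


def fit_monoexp(curve: SignalCurve, b_t: float) -> MonoExpFit:
    """Least-squares fit of ``ln S = ln S_int - b D`` over ``b >= b_t``.

    Closed-form linear regression on the log signal; non-positive signal
    values are excluded.  Raises :class:`InsufficientDataError` with fewer
    than 3 usable points.
    """
    sel = curve.bvalues >= b_t
    b = curve.bvalues[sel]
    s = curve.signal[sel]
    pos = s > 0
    b, s = b[pos], s[pos]
    if b.size < 3:
        raise InsufficientDataError(
            f"mono-exponential fit needs >= 3 positive-signal points with b >= {b_t}, got {b.size}"
        )
    slope, intercept = np.polyfit(b, np.log(s), 1)
    return MonoExpFit(D_tilde=float(-slope), S_int=float(np.exp(intercept)), b_t=float(b_t))


def compute_f_tilde(curve: SignalCurve, D: float) -> PseudoDiffusionCurve:
    """Transform the decay curve into the pseudo-diffusion residual f~(b).

    ``f~(b) = 1 - [S(b)/S(0)] e^{bD}``.  For a noiseless curve with exact D
    this equals ``f (1 - e^{-b D*})`` identically.  Values may be negative
    under noise; they are retained (the eps term of the AS fit absorbs offset
    error, and clipping would bias f0).
    """
    if not np.isfinite(D) or D < 0:
        raise InputDomainError(f"D must be finite and >= 0, got {D}")
    ft = 1.0 - (curve.signal / curve.S0) * np.exp(curve.bvalues * D)
    ft[0] = 0.0  # exact at b = 0 regardless of rounding
    return PseudoDiffusionCurve(bvalues=curve.bvalues, f_tilde=ft)


def _bounded_lsq(residual, x0, lower, upper):
    """Trust-region least squares; returns (x, success)."""
    x0 = np.clip(x0, lower, upper)
    try:
        res = least_squares(residual, x0, bounds=(lower, upper), method="trf")
        return res.x, bool(res.success)
    except Exception:  # pragma: no cover - scipy failures are rare
        return np.asarray(x0, dtype=float), False


def _f_init(S_int: float, S0: float) -> float:
    return float(min(max(1.0 - S_int / S0, 0.01), 1.0))


def _dstar_init(D: float, floor: float) -> float:
    return float(min(max(10.0 * D, floor), DSTAR_MAX * 0.5))


def _package(method, D_raw, f_raw, ds_raw, intermediates, converged, msgs):
    """Assemble a FitResult: raw estimates plus physically clipped params."""
    D_phys = max(D_raw, 0.0)
    f_phys = min(max(f_raw, 0.0), 1.0)
    if D_phys != D_raw:
        msgs.append(f"D clipped to 0 (raw {D_raw:.3e})")
    if f_phys != f_raw:
        msgs.append(f"f clipped to {f_phys:g} (raw {f_raw:.4g})")
    params = IVIMParams(D=D_phys, Dstar=ds_raw, f=f_phys)
    estimates = {"D": D_raw, "Dstar": ds_raw, "f": f_raw, "flux": f_raw * ds_raw}
    return FitResult(
        method=method,
        params=params,
        estimates=estimates,
        intermediates=intermediates,
        converged=converged,
        message="; ".join(msgs),
    )


def fit_S(curve: SignalCurve, b_t: float) -> FitResult:
    """Segmented fit: D from the tail, then (f, D*) with D and S(0) fixed."""
    msgs: list = []
    mono = fit_monoexp(curve, b_t)
    D = max(mono.D_tilde, 0.0)
    S0 = curve.S0
    b, s = curve.bvalues, curve.signal
    ds_lo = _dstar_floor(b[-1])

    def residual(x):
        f, ds = x
        return (
            S0 * (f * np.exp(-b * (D + ds)) + (1.0 - f) * np.exp(-b * D)) - s
        )

    x0 = [_f_init(mono.S_int, S0), _dstar_init(D if D > 0 else 1e-3, ds_lo)]
    x, ok = _bounded_lsq(
        residual, x0, [F_FIT_BOUNDS[0], ds_lo], [F_FIT_BOUNDS[1], DSTAR_MAX]
    )
    if not ok:
        msgs.append("stage-2 optimizer did not converge; initial values returned")
    return _package("S", mono.D_tilde, float(x[0]), float(x[1]), {"mono": mono}, ok, msgs)


def fit_OS(curve: SignalCurve, b_t: float) -> FitResult:
    """Oversegmented fit: f = 1 - S_int/S(0); only D* fitted nonlinearly."""
    msgs: list = []
    mono = fit_monoexp(curve, b_t)
    D = max(mono.D_tilde, 0.0)
    S0 = curve.S0
    f = 1.0 - mono.S_int / S0
    b, s = curve.bvalues, curve.signal
    ds_lo = _dstar_floor(b[-1])

    if f <= 0.0:
        # no perfusion signal to explain: model independent of D*
        msgs.append("f at or below 0: D* reported at lower bound")
        return _package("OS", mono.D_tilde, f, ds_lo, {"mono": mono, "f0": f}, True, msgs)

    def residual(x):
        return S0 * (f * np.exp(-b * (D + x[0])) + (1.0 - f) * np.exp(-b * D)) - s

    x0 = [_dstar_init(D if D > 0 else 1e-3, ds_lo)]
    x, ok = _bounded_lsq(residual, x0, [ds_lo], [DSTAR_MAX])
    if not ok:
        msgs.append("stage-2 optimizer did not converge; initial values returned")
    return _package("OS", mono.D_tilde, f, float(x[0]), {"mono": mono, "f0": f}, ok, msgs)


def _fit_f_tilde_stage(curve: SignalCurve, D: float, f_init: float | None = None):
    """Fit f~(b) = f0 (1 - e^{-b D*}) + eps over all acquired b-values.

    With ``f_init`` omitted the start value is the mean of the last four f~
    points — the model's own asymptote estimate.  Returns
    (f0, Dstar, eps, ok, curve).
    """
    ftc = compute_f_tilde(curve, D)
    b, ft = ftc.bvalues, ftc.f_tilde
    ds_lo = _dstar_floor(b[-1])
    if f_init is None:
        f_init = float(np.clip(np.mean(ft[-4:]), F_FIT_BOUNDS[0] + 0.01, F_FIT_BOUNDS[1]))

    def residual(x):
        return x[0] * (1.0 - np.exp(-b * x[1])) + x[2] - ft

    x0 = [f_init, _dstar_init(D if D > 0 else 1e-3, ds_lo), 0.0]
    lower = [F_FIT_BOUNDS[0], ds_lo, EPS_BOUNDS[0]]
    upper = [F_FIT_BOUNDS[1], DSTAR_MAX, EPS_BOUNDS[1]]
    x, ok = _bounded_lsq(residual, x0, lower, upper)
    return float(x[0]), float(x[1]), float(x[2]), ok, ftc


def fit_AS(curve: SignalCurve, b_t: float) -> FitResult:
    """Analytical segmented fit with the eps offset term; f estimate = f0."""
    msgs: list = []
    mono = fit_monoexp(curve, b_t)
    D = max(mono.D_tilde, 0.0)
    f0, Dstar, eps, ok, _ = _fit_f_tilde_stage(curve, D, _f_init(mono.S_int, curve.S0))
    if not ok:
        msgs.append("f~ fit did not converge; initial values returned")
    inter = {"mono": mono, "f0": f0, "epsilon": eps}
    return _package("AS", mono.D_tilde, f0, Dstar, inter, ok, msgs)


def default_bt_series(bvalues: np.ndarray, min_points: int = 4) -> np.ndarray:
    """Thresholds leaving at least ``min_points`` b-values in the tail."""
    b = np.asarray(bvalues, dtype=float)
    return np.array([bt for bt in b if np.count_nonzero(b >= bt) >= min_points])


def estimate_D_opAS(curve: SignalCurve, bt_series=None) -> OpASDEstimate:
    """Threshold-free D estimate from the trend of mono-exponential fits.

    Computes ``D~(b_t)`` for each threshold in ``bt_series`` (default: every
    acquired b-value leaving >= 4 tail points), fits
    ``D~(b_t) = ADC - P (1 - e^{-b_t D*_tmp})`` with free (ADC, P, D*_tmp),
    and returns ``D = ADC - P``, the b_t -> infinity limit.  ``D*_tmp`` only
    shapes this trend; the final D* comes from the subsequent f~ stage.
    """
    if bt_series is None:
        bt_series = default_bt_series(curve.bvalues)
    bt_series = np.asarray(bt_series, dtype=float)
    if bt_series.size < 4:
        raise InsufficientDataError(f"opAS needs >= 4 b_t values, got {bt_series.size}")
    d_tilde = np.array([fit_monoexp(curve, bt).D_tilde for bt in bt_series])
    dtmp_lo = _dstar_floor(bt_series[-1])

    def residual(x):
        return x[0] - x[1] * (1.0 - np.exp(-bt_series * x[2])) - d_tilde

    x0 = [
        d_tilde[0],
        max(d_tilde[0] - d_tilde[-1], 1e-6),
        _dstar_init(max(d_tilde[-1], 1e-4), dtmp_lo),
    ]
    lower = [ADC_BOUNDS[0], P_BOUNDS[0], dtmp_lo]
    upper = [ADC_BOUNDS[1], P_BOUNDS[1], DSTAR_MAX]
    x, ok = _bounded_lsq(residual, x0, lower, upper)
    if ok:
        return OpASDEstimate(float(x[0] - x[1]), float(x[0]), float(x[1]), float(x[2]), True)
    # fallback: the least-contaminated single-threshold estimate
    return OpASDEstimate(float(d_tilde[-1]), float(d_tilde[0]), 0.0, 0.0, False)


def fit_opAS(curve: SignalCurve, bt_series=None) -> FitResult:
    """Optimized analytical segmented fit; no b-threshold argument."""
    msgs: list = []
    est = estimate_D_opAS(curve, bt_series)
    if not est.converged:
        msgs.append("ADC-trend fit did not converge; D taken from max-b_t tail fit")
    f0, Dstar, eps, ok, _ = _fit_f_tilde_stage(curve, max(est.D, 0.0))
    if not ok:
        msgs.append("f~ fit did not converge; initial values returned")
    inter = {
        "f0": f0,
        "epsilon": eps,
        "ADC": est.ADC,
        "fD_product": est.fD_product,
        "Dstar_tmp": est.Dstar_tmp,
    }
    return _package("opAS", est.D, f0, Dstar, inter, ok and est.converged, msgs)


def fit_curve(curve: SignalCurve, method: str, b_t: float | None = None) -> FitResult:
    """Dispatch to one of the four fitters.

    ``b_t`` is required for S/OS/AS and ignored for opAS, which is
    threshold-free by construction.
    """
    if method not in METHODS:
        raise ConfigError(f"unknown method {method!r}; choose one of {METHODS}")
    if method == "opAS":
        return fit_opAS(curve)
    if b_t is None:
        raise ConfigError(f"method {method!r} requires a b_t threshold")
    if method == "S":
        return fit_S(curve, b_t)
    if method == "OS":
        return fit_OS(curve, b_t)
    return fit_AS(curve, b_t)


def _result_row(rid, res: FitResult) -> dict:
    inter = res.intermediates
    return {
        "id": rid,
        "method": res.method,
        "D": res.estimates["D"],
        "Dstar": res.estimates["Dstar"],
        "f": res.estimates["f"],
        "flux": res.estimates["flux"],
        "f0": inter.get("f0", np.nan),
        "epsilon": inter.get("epsilon", np.nan),
        "ADC": inter.get("ADC", np.nan),
        "converged": res.converged,
    }


def _nan_row(rid, method) -> dict:
    return {
        "id": rid,
        "method": method,
        "D": np.nan,
        "Dstar": np.nan,
        "f": np.nan,
        "flux": np.nan,
        "f0": np.nan,
        "epsilon": np.nan,
        "ADC": np.nan,
        "converged": False,
    }


def fit_batch(frame, method: str, b_t: float | None = None):
    """Fit many curves given a long table with columns ``id, b, signal``.

    Returns a :class:`pandas.DataFrame` with one row per curve carrying the
    raw estimates (columns: id, method, D, Dstar, f, flux, f0, epsilon, ADC,
    converged).  Curves that cannot be fitted at all yield a row of NaNs with
    ``converged=False``.
    """
    import pandas as pd

    rows = []
    for rid, grp in frame.groupby("id", sort=True):
        try:
            curve = SignalCurve.from_measurements(
                grp["b"].to_numpy(), grp["signal"].to_numpy()
            )
            rows.append(_result_row(rid, fit_curve(curve, method, b_t)))
        except (InputDomainError, InsufficientDataError):
            rows.append(_nan_row(rid, method))
    return pd.DataFrame(rows)
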