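"""Accuracy and precision metrics for replicate parameter estimates.

For N estimates ``theta_i`` of a true value ``theta_T``:

* NME  (normalized mean error, signed bias)
  ``(1/N) sum_i (theta_i - theta_T) / theta_T``
* CoV  (coefficient of variation, precision)
  ``sqrt((1/N) sum_i (theta_i - <theta>)^2) / |<theta>|`` — note the
  population (1/N) variance, not the 1/(N-1) sample variance.  The
  magnitude of the mean is used in the denominator so that the CoV stays a
  non-negative dispersion measure even when raw estimates of a near-zero
  parameter average slightly negative.
* NRMSE (total error)
  ``sqrt((1/N) sum_i (theta_i - theta_T)^2) / theta_T``

These satisfy ``NRMSE^2 = NME^2 + (population variance / theta_T^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import InputDomainError

__all__ = [
    "EstimateSample",
    "MetricSet",
    "nme",
    "cov",
    "nrmse",
    "metric_set",
    "summarize_grid",
    "PARAMETERS",
]

PARAMETERS = ("D", "Dstar", "f", "flux")


@dataclass(frozen=True)
class EstimateSample:
    """Replicate estimates of one parameter together with its true value."""

    values: np.ndarray
    truth: float
    parameter_name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size < 1:
            raise InputDomainError("need at least one estimate")


@dataclass(frozen=True)
class MetricSet:
    nme: float
    cov: float
    nrmse: float
    n: int


def _values_truth(sample, truth):
    if isinstance(sample, EstimateSample):
        return sample.values, sample.truth
    return np.asarray(sample, dtype=float), truth


def nme(sample, truth: float | None = None) -> float:
    """Signed normalized mean error; negative means underestimation."""
    v, t = _values_truth(sample, truth)
    if t == 0:
        raise InputDomainError("truth must be nonzero for normalized metrics")
    return float(np.mean((v - t) / t))


def cov(sample, truth: float | None = None) -> float:
    """Population coefficient of variation of the estimates (always >= 0)."""
    v, _ = _values_truth(sample, truth)
    m = np.mean(v)
    if m == 0:
        raise InputDomainError("sample mean is zero; CoV undefined")
    return float(np.sqrt(np.mean((v - m) ** 2)) / abs(m))


def nrmse(sample, truth: float | None = None) -> float:
    """Root-mean-square error normalized by the true value."""
    v, t = _values_truth(sample, truth)
    if t == 0:
        raise InputDomainError("truth must be nonzero for normalized metrics")
    return float(np.sqrt(np.mean(((v - t) / t) ** 2)))


def metric_set(sample: EstimateSample) -> MetricSet:
    return MetricSet(
        nme=nme(sample), cov=cov(sample), nrmse=nrmse(sample), n=int(sample.values.size)
    )


def summarize_grid(
    results: pd.DataFrame,
    spec=None,
    exclude_nonconverged: bool = False,
):
    """Tabulate NME/CoV/NRMSE over a simulation grid of fit results.

    Parameters
    ----------
    results : DataFrame
        One row per replicate fit with columns ``f_true, Dstar_true, D_true,
        snr, method, b_t, rep, D, Dstar, f, flux, converged``.  ``b_t`` is
        NaN for threshold-free methods.
    spec : SimulationSpec, optional
        When given, every (f, Dstar, snr) grid cell the spec defines is
        checked for presence; missing cells are listed in the returned
        completeness report rather than silently dropped.
    exclude_nonconverged : bool
        Recompute the metrics using only converged replicates (sensitivity
        analysis).  By default every replicate is included.

    Returns
    -------
    table : DataFrame
        Long format, one row per (parameter, f_true, Dstar_true, snr, method,
        b_t) with columns nme, cov, nrmse, n.  Suitable for pivoting into the
        f-by-D* heatmap layout (f increasing vertically, D* horizontally).
    missing : list of tuple
        Grid cells (f, Dstar, snr) absent from ``results``.
    """
    df = results
    if exclude_nonconverged:
        df = df[df["converged"]]

    truth_col = {"D": "D_true", "Dstar": "Dstar_true", "f": "f_true", "flux": None}
    keys = ["f_true", "Dstar_true", "snr", "method", "b_t"]
    work = df.copy()
    work["b_t"] = work["b_t"].fillna(-1.0)  # NaN keys would drop groups
    rows = []
    for cell, grp in work.groupby(keys, sort=True):
        f_true, dstar_true, snr, method, b_t = cell
        truths = {
            "D": grp["D_true"].iloc[0],
            "Dstar": dstar_true,
            "f": f_true,
            "flux": f_true * dstar_true,
        }
        for param in PARAMETERS:
            sample = EstimateSample(grp[param].to_numpy(), truths[param], param)
            try:
                ms = metric_set(sample)
            except InputDomainError:
                ms = MetricSet(np.nan, np.nan, np.nan, int(sample.values.size))
            rows.append(
                {
                    "parameter": param,
                    "f_true": f_true,
                    "Dstar_true": dstar_true,
                    "snr": snr,
                    "method": method,
                    "b_t": b_t if b_t >= 0 else np.nan,
                    "nme": ms.nme,
                    "cov": ms.cov,
                    "nrmse": ms.nrmse,
                    "n": ms.n,
                }
            )
    table = pd.DataFrame(rows)

    missing = []
    if spec is not None:
        have = set(
            zip(results["f_true"].round(10), results["Dstar_true"].round(10), results["snr"])
        )
        for f in spec.f_grid:
            for ds in spec.Dstar_grid:
                for snr in spec.snr_levels:
                    if (round(float(f), 10), round(float(ds), 10), snr) not in have:
                        missing.append((float(f), float(ds), float(snr)))
    return table, missing


def render_heatmaps(table: pd.DataFrame, metric: str, outpath, snr=None):
    """Render the per-method f-by-D* heatmap grid of one metric to PNG.

    Rows of each panel are f values (increasing upward), columns D* values
    (increasing rightward), one panel per (method, b_t).  Requires
    matplotlib; figures are a convenience view — CSV tables are canonical.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table[table["parameter"].notna()]
    if snr is not None:
        sub = sub[sub["snr"] == snr]
    combos = sub[["method", "b_t"]].drop_duplicates().itertuples(index=False)
    combos = list(combos)
    params = [p for p in PARAMETERS if p in set(sub["parameter"])]
    fig, axes = plt.subplots(
        len(params), len(combos), figsize=(3 * len(combos), 2.5 * len(params)), squeeze=False
    )
    for i, param in enumerate(params):
        for j, (method, b_t) in enumerate(combos):
            sel = sub[(sub["parameter"] == param) & (sub["method"] == method)]
            sel = sel[sel["b_t"].isna()] if np.isnan(b_t) else sel[sel["b_t"] == b_t]
            pivot = sel.pivot_table(index="f_true", columns="Dstar_true", values=metric)
            ax = axes[i][j]
            ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto", cmap="RdBu_r")
            label = method if np.isnan(b_t) else f"{method} b_t={b_t:g}"
            ax.set_title(f"{param} {label}", fontsize=8)
            ax.set_xticks([])
            ax.set_yticks([])
    fig.suptitle(metric)
    fig.tight_layout()
    fig.savefig(outpath, dpi=120)
    plt.close(fig)
    return outpath
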