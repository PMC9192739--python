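"""Protein preprocessing: Box-Cox transform, scaling, extreme-outlier rule.

The pipeline normalizes each analyte with a Box-Cox power transform (lambda
chosen by profile maximum likelihood on a fixed grid), centers and scales it
to mean 0 / SD 1, and then applies a two-level extreme-value exclusion: each
analyte's 99th-percentile cutoff is computed on the scaled data, the 99.5th
percentile of those cutoffs across analytes becomes one global threshold,
and any value above it is set to missing for that analyte (values are
removed, never whole samples). All percentiles use the linear-interpolation
quantile convention, everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ProteinMatrix

__all__ = ["PrepReport", "boxcox_transform", "exclude_outliers"]

# profile-likelihood grid for the Box-Cox exponent
LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 10)


@dataclass
class PrepReport:
    """Per-analyte transform parameters and outlier accounting.

    ``global_threshold`` is the 99.5th percentile of the per-analyte
    99th-percentile cutoffs; once set it is frozen, making the exclusion
    idempotent.
    """

    lambdas: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    shifts: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    constant_analytes: list = field(default_factory=list)
    analyte_cutoffs: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    global_threshold: float | None = None
    excluded_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))


def _boxcox_profile_llf(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Profile log-likelihood of the Box-Cox exponent over ``grid``.

    Vectorized over the grid; the sigma^2 MLE is profiled out analytically.
    """
    n = len(x)
    logx = np.log(x)
    lam = grid[:, None]
    with np.errstate(over="ignore", invalid="ignore"):
        y = np.where(np.abs(lam) < 1e-12, logx[None, :],
                     (np.power(x[None, :], lam) - 1.0) / lam)
    var = y.var(axis=1)
    var = np.where(var <= 0, np.nan, var)
    return -0.5 * n * np.log(var) + (grid - 1.0) * logx.sum()


def boxcox_transform(matrix: ProteinMatrix) -> tuple[ProteinMatrix, PrepReport]:
    """Box-Cox transform each analyte, then center/scale to mean 0, SD 1.

    Nonpositive analytes are shifted by ``1 - min`` first (recorded in the
    report). A constant analyte has no defined lambda; it is flagged and
    passed through centered at 0. Requires ``state == "raw"``. The transform
    is strictly monotone per analyte, so rank order is preserved.
    """
    if matrix.state != "raw":
        raise ValueError("boxcox_transform expects raw-state protein data")
    values = matrix.values
    out = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    lambdas, shifts, constant = {}, {}, []
    for aid in values.columns:
        col = values[aid].to_numpy(dtype=float)
        obs = ~np.isnan(col)
        x = col[obs]
        shift = 0.0
        if x.size and x.min() <= 0:
            shift = 1.0 - float(x.min())
            x = x + shift
        shifts[aid] = shift
        if x.size == 0 or np.all(x == x[0]):
            constant.append(aid)
            lambdas[aid] = np.nan
            out[aid] = np.where(obs, 0.0, np.nan)
            continue
        llf = _boxcox_profile_llf(x, LAMBDA_GRID)
        lam = float(LAMBDA_GRID[np.nanargmax(llf)])
        lambdas[aid] = lam
        y = np.log(x) if abs(lam) < 1e-12 else (np.power(x, lam) - 1.0) / lam
        y = (y - y.mean()) / y.std()
        full = np.full(len(col), np.nan)
        full[obs] = y
        out[aid] = full
    report = PrepReport(lambdas=pd.Series(lambdas), shifts=pd.Series(shifts),
                        constant_analytes=constant)
    return (ProteinMatrix(out, matrix.annotation, state="transformed",
                          confounder=matrix.confounder), report)


def exclude_outliers(matrix: ProteinMatrix,
                     report: PrepReport) -> tuple[ProteinMatrix, PrepReport]:
    """Apply the two-level extreme-outlier rule on scaled data.

    Per analyte the 99th percentile is computed; the 99.5th percentile of
    those cutoffs across all analytes is a single global threshold, and
    values above it become missing for their analyte only. The threshold is
    stored in the report and reused on any later pass (so a second
    application removes nothing). Fewer than two analytes leave the global
    percentile undefined and raise ``ValueError``.
    """
    if matrix.state != "transformed":
        raise ValueError("exclude_outliers expects transformed (scaled) data")
    if matrix.values.shape[1] < 2:
        raise ValueError("global outlier threshold undefined for < 2 analytes")
    values = matrix.values.copy()
    cutoffs = values.quantile(0.99)  # linear-interpolation quantile
    if report.global_threshold is None:
        threshold = float(np.quantile(cutoffs.to_numpy(dtype=float), 0.995))
    else:
        threshold = report.global_threshold
    mask = values > threshold
    counts = mask.sum()
    values[mask] = np.nan
    report.analyte_cutoffs = cutoffs
    report.global_threshold = threshold
    report.excluded_counts = counts
    return (ProteinMatrix(values, matrix.annotation, state="transformed",
                          confounder=matrix.confounder), report)
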