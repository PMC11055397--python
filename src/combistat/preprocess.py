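"""Log transformation, the four normalization methods, and QC summary tables.

All normalizations preserve matrix shape, protein/sample orderings and the
missing mask.  Median and quantile normalization operate on log-scale values;
internal reference scaling (iRS) and the variance-stabilizing glog transform
consume raw intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, rankdata

from .core_data import (LOG2, LOG10, RAW, CombistatError, ExpressionMatrix,
                        MetadataTable, align_metadata)


@dataclass(frozen=True)
class NormalizationConfig:
    method: str = "median"        # median | quantile | irs | vsn_glog
    log_base: int | None = 2      # 2 | 10 | None

    def __post_init__(self):
        if self.method not in ("median", "quantile", "irs", "vsn_glog"):
            raise CombistatError(f"unknown normalization method {self.method!r}")
        if self.log_base not in (2, 10, None):
            raise CombistatError("log_base must be 2, 10 or None")


# -- transformation ----------------------------------------------------------

def log_transform(matrix: ExpressionMatrix, base: int = 2,
                  nonpositive: str = "error") -> ExpressionMatrix:
    """Cell-wise logarithm (base 2 or 10) of a raw-scale matrix.

    ``nonpositive`` controls observed values <= 0: ``"error"`` raises with the
    cell address, ``"mask"`` converts them to missing.
    """
    if matrix.scale_tag != RAW:
        raise CombistatError(f"matrix is already on {matrix.scale_tag} scale")
    if base not in (2, 10):
        raise CombistatError("log base must be 2 or 10")
    values = matrix.values.copy()
    bad = (values <= 0) & ~np.isnan(values)
    if bad.any():
        if nonpositive == "error":
            i, j = np.argwhere(bad)[0]
            raise CombistatError(
                f"non-positive value {values[i, j]} at protein "
                f"{matrix.protein_ids[i]!r}, sample {matrix.sample_ids[j]!r}; "
                "use nonpositive='mask' to convert to missing"
            )
        values[bad] = np.nan
    with np.errstate(invalid="ignore"):
        out = np.log2(values) if base == 2 else np.log10(values)
    return matrix.with_values(out, LOG2 if base == 2 else LOG10)


def delog(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Invert the log transform (back to raw intensities)."""
    if matrix.scale_tag == RAW:
        return matrix.copy()
    base = 2.0 if matrix.scale_tag == LOG2 else 10.0
    return matrix.with_values(base ** matrix.values, RAW)


def _require_logged(matrix: ExpressionMatrix, op: str) -> None:
    if matrix.scale_tag not in (LOG2, LOG10):
        raise CombistatError(f"{op} expects a log-transformed matrix "
                             f"(scale_tag is {matrix.scale_tag!r})")


def _require_observed(values: np.ndarray, sample_ids, min_obs: int = 1) -> None:
    counts = (~np.isnan(values)).sum(axis=0)
    for sid, c in zip(sample_ids, counts):
        if c < min_obs:
            raise CombistatError(
                f"sample {sid!r} has {c} observed values (need >= {min_obs})")


# -- normalization -----------------------------------------------------------

def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Shift each sample additively so its observed median equals the grand
    median of the original per-sample medians.  Missing cells untouched."""
    _require_logged(matrix, "median_normalize")
    values = matrix.values.copy()
    _require_observed(values, matrix.sample_ids)
    medians = np.nanmedian(values, axis=0)
    target = np.median(medians)
    values = values - medians[np.newaxis, :] + target
    return matrix.with_values(values)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample's observed values onto a common reference
    distribution (the mean across samples of each order statistic).

    Missing values are handled by ranking observed values within each sample
    and interpolating the reference distribution — built on a grid of length
    equal to the largest observed count — at each sample's quantile
    positions.  Ties within a sample receive the mean of the reference values
    at their tied ranks.  On a complete matrix this reduces to textbook
    quantile normalization.
    """
    _require_logged(matrix, "quantile_normalize")
    values = matrix.values.copy()
    _require_observed(values, matrix.sample_ids)
    n_prot, n_samp = values.shape
    counts = (~np.isnan(values)).sum(axis=0)
    grid_len = int(counts.max())
    grid_q = np.linspace(0.0, 1.0, grid_len)

    # reference distribution: per-sample sorted values interpolated to the grid
    ref = np.zeros(grid_len)
    for j in range(n_samp):
        obs = np.sort(values[~np.isnan(values[:, j]), j])
        if len(obs) == 1:
            ref += obs[0]
        else:
            q = np.linspace(0.0, 1.0, len(obs))
            ref += np.interp(grid_q, q, obs)
    ref /= n_samp

    out = values.copy()
    for j in range(n_samp):
        col = values[:, j]
        idx = ~np.isnan(col)
        obs = col[idx]
        m = len(obs)
        # average ranks handle ties: tied cells share the mean reference value
        ranks = rankdata(obs, method="average")  # 1..m
        q = (ranks - 1.0) / (m - 1.0) if m > 1 else np.zeros_like(ranks)
        out[idx, j] = np.interp(q, grid_q, ref)
    return matrix.with_values(out)


def irs_normalize(matrix: ExpressionMatrix, meta: MetadataTable) -> ExpressionMatrix:
    """Internal reference scaling across batches/plexes (raw scale).

    Per protein and batch, a reference abundance is computed from the batch's
    flagged reference channels (mean), or from all of the batch's samples when
    none are flagged.  The geometric mean of the per-batch references is the
    target; every sample in a batch is multiplied by target/reference for that
    protein.  Proteins unobserved in a batch's reference stay missing there.
    """
    if matrix.scale_tag != RAW:
        raise CombistatError("irs_normalize operates on raw-scale intensities")
    meta = align_metadata(matrix, meta)
    batches = meta.batches()
    if len(batches) < 2:
        raise CombistatError("iRS requires >=2 batches")
    values = matrix.values.copy()
    col_index = {s: j for j, s in enumerate(matrix.sample_ids)}

    refs = np.full((matrix.n_proteins, len(batches)), np.nan)
    batch_cols: list[list[int]] = []
    for b, batch in enumerate(batches):
        ref_samples = meta.reference_samples(batch) or meta.samples_in_batch(batch)
        cols = [col_index[s] for s in ref_samples]
        if not cols:
            raise CombistatError(f"batch {batch!r} has no samples")
        sub = values[:, cols]
        cnt = (~np.isnan(sub)).sum(axis=1)
        tot = np.nansum(sub, axis=1)
        refs[:, b] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
        batch_cols.append([col_index[s] for s in meta.samples_in_batch(batch)])
        if np.isnan(refs[:, b]).all():
            raise CombistatError(
                f"batch {batch!r} has no observed reference value for any protein")

    with np.errstate(invalid="ignore", divide="ignore"):
        log_refs = np.log(refs)
        n_obs = (~np.isnan(log_refs)).sum(axis=1)
        log_tot = np.nansum(np.where(np.isnan(log_refs), 0.0, log_refs), axis=1)
        target = np.where(n_obs > 0, np.exp(log_tot / np.maximum(n_obs, 1)), np.nan)
        for b in range(len(batches)):
            factor = target / refs[:, b]          # NaN where reference unobserved
            for j in batch_cols[b]:
                values[:, j] = values[:, j] * factor
    return matrix.with_values(values)


# -- variance-stabilizing glog ----------------------------------------------

def _lts_affine(x: np.ndarray, y: np.ndarray, keep: float = 0.75,
                n_iter: int = 5) -> tuple[float, float]:
    """Least-trimmed-squares affine fit y ≈ a + b·x (iterated trimmed OLS)."""
    idx = np.arange(len(x))
    a, b = 0.0, 1.0
    for _ in range(n_iter):
        xs, ys = x[idx], y[idx]
        b, a = np.polyfit(xs, ys, 1)
        resid = (y - (a + b * x)) ** 2
        m = max(int(np.ceil(keep * len(x))), 3)
        idx = np.argsort(resid)[:m]
    return a, b


def vsn_glog_normalize(matrix: ExpressionMatrix, *, max_iter: int = 50,
                       tol: float = 1e-6) -> ExpressionMatrix:
    """Simplified variance-stabilizing normalization.

    Each sample receives an affine calibration followed by a generalized-log
    transform h(x) = arsinh((x − a_s)/b_s).  Per-sample offsets/gains are
    estimated by iterating a least-trimmed-squares fit of each sample against
    the row means of the calibrated matrix; the glog scale is set to the
    additive/multiplicative noise-ratio estimate so that variance decouples
    from mean intensity.  This is a documented simplification, not a
    re-implementation of the vsn2 package.
    """
    if matrix.scale_tag != RAW:
        raise CombistatError("vsn_glog_normalize operates on raw intensities")
    if matrix.n_proteins < 10:
        raise CombistatError("vsn_glog needs >=10 proteins to calibrate")
    values = matrix.values
    n_samp = matrix.n_samples
    offsets = np.zeros(n_samp)
    gains = np.ones(n_samp)

    complete = ~np.isnan(values).any(axis=1)
    if complete.sum() < 10:
        raise CombistatError("vsn_glog needs >=10 complete proteins to calibrate")
    X = values[complete]

    for _ in range(max_iter):
        calib = (X - offsets) / gains
        consensus = calib.mean(axis=1)
        new_off = np.empty(n_samp)
        new_gain = np.empty(n_samp)
        for j in range(n_samp):
            a, b = _lts_affine(consensus, X[:, j])
            new_off[j] = a
            new_gain[j] = b if abs(b) > 1e-12 else 1.0
        delta = max(np.abs(new_off - offsets).max(), np.abs(new_gain - gains).max())
        offsets, gains = new_off, new_gain
        if delta < tol:
            break

    calib = (X - offsets) / gains
    consensus = calib.mean(axis=1)
    resid_sd = calib.std(axis=1, ddof=1)
    order = np.argsort(consensus)
    lo = order[: max(len(order) // 5, 5)]
    hi = order[-max(len(order) // 5, 5):]
    sigma_add = float(np.median(resid_sd[lo]))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_hi = resid_sd[hi] / np.abs(consensus[hi])
    sigma_mult = float(np.median(cv_hi[np.isfinite(cv_hi)]))
    if not np.isfinite(sigma_mult) or sigma_mult <= 1e-9:
        b_glog = max(sigma_add, 1.0)
    else:
        b_glog = max(sigma_add / sigma_mult, 1e-9)

    a_s = offsets
    b_s = gains * b_glog
    out = np.arcsinh((values - a_s[np.newaxis, :]) / b_s[np.newaxis, :])
    # report on log2-comparable scale: arsinh differs from ln by a constant
    # asymptotically; divide by ln 2 so downstream logFCs stay in log2 units
    out = out / np.log(2.0)
    return matrix.with_values(out, LOG2)


# -- QC ----------------------------------------------------------------------

@dataclass
class QCTables:
    five_number: pd.DataFrame      # sample × {min, q1, median, q3, max}
    density: pd.DataFrame          # long: sample, x, density
    missing_counts: pd.Series


def qc_summary(matrix: ExpressionMatrix, density_points: int = 128) -> QCTables:
    """Per-sample five-number summary, kernel-density grid and missing counts,
    as plain tables any plotting layer can consume."""
    values = matrix.values
    rows = {}
    dens_rows = []
    for j, sid in enumerate(matrix.sample_ids):
        obs = values[~np.isnan(values[:, j]), j]
        if len(obs) == 0:
            rows[sid] = [np.nan] * 5
            continue
        q = np.percentile(obs, [0, 25, 50, 75, 100])
        rows[sid] = list(q)
        if len(obs) >= 3 and np.ptp(obs) > 0:
            kde = gaussian_kde(obs)
            pad = 3 * kde.factor * obs.std(ddof=1)
            grid = np.linspace(obs.min() - pad, obs.max() + pad, density_points)
            d = kde(grid)
        else:
            grid = np.linspace(obs.min() - 1, obs.max() + 1, density_points)
            d = np.zeros_like(grid)
        dens_rows.append(pd.DataFrame({"sample": sid, "x": grid, "density": d}))
    five = pd.DataFrame.from_dict(
        rows, orient="index", columns=["min", "q1", "median", "q3", "max"])
    five.index.name = "sample"
    density = (pd.concat(dens_rows, ignore_index=True)
               if dens_rows else pd.DataFrame(columns=["sample", "x", "density"]))
    missing = pd.Series(np.isnan(values).sum(axis=0), index=matrix.sample_ids,
                        name="n_missing")
    return QCTables(five, density, missing)
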