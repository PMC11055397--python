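"""Missing-value imputation: downshifted-normal draws, protein-wise kNN, and
iterative random-forest (missForest-style) chained imputation.

All methods leave observed cells bit-identical and return a matrix with zero
missing cells (or raise).  The downshifted normal targets left-censored
(missing-not-at-random) label-free data: missing cells in sample *s* are drawn
from Normal(μ_s − shift·σ_s, (width·σ_s)²) using that sample's observed
moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .core_data import CombistatError, ExpressionMatrix, LOG2, LOG10

DEFAULT_SHIFT = 1.8   # per-sample SD units below the observed mean
DEFAULT_WIDTH = 0.3   # SD multiplier of the imputation distribution


@dataclass(frozen=True)
class ImputeConfig:
    method: str = "normal_draw"   # normal_draw | knn | iterative_forest
    shift: float = DEFAULT_SHIFT
    width: float = DEFAULT_WIDTH
    k: int = 10
    max_iter: int = 10
    n_trees: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.method not in ("normal_draw", "knn", "iterative_forest"):
            raise CombistatError(f"unknown imputation method {self.method!r}")
        if self.shift < 0:
            raise CombistatError("shift must be >= 0")
        if not (0 < self.width <= 1):
            raise CombistatError("width must be in (0, 1]")
        if self.k < 1:
            raise CombistatError("k must be >= 1")
        if self.method in ("normal_draw", "iterative_forest") and self.seed is None:
            raise CombistatError(f"{self.method} is stochastic; a seed is required")


def _require_logged(matrix: ExpressionMatrix) -> None:
    if matrix.scale_tag not in (LOG2, LOG10):
        raise CombistatError("imputation expects a log-transformed matrix")


def impute(matrix: ExpressionMatrix, config: ImputeConfig) -> ExpressionMatrix:
    """Dispatch on ``config.method``."""
    if config.method == "normal_draw":
        return impute_normal_draw(matrix, config)
    if config.method == "knn":
        return impute_knn(matrix, config)
    return impute_iterative_forest(matrix, config)


# -- downshifted normal ------------------------------------------------------

def impute_normal_draw(matrix: ExpressionMatrix, config: ImputeConfig) -> ExpressionMatrix:
    _require_logged(matrix)
    values = matrix.values.copy()
    mask = np.isnan(values)
    if not mask.any():
        return matrix.copy()
    rng = np.random.default_rng(config.seed)
    for j, sid in enumerate(matrix.sample_ids):
        obs = values[~mask[:, j], j]
        if len(obs) < 2:
            raise CombistatError(
                f"sample {sid!r} has {len(obs)} observed values; "
                "downshifted-normal imputation needs >=2")
        mu, sd = obs.mean(), obs.std(ddof=1)
        n_miss = int(mask[:, j].sum())
        if n_miss:
            draws = rng.normal(mu - config.shift * sd, config.width * sd, size=n_miss)
            values[mask[:, j], j] = draws
    return matrix.with_values(values)


# -- protein-wise k-nearest neighbours --------------------------------------

def impute_knn(matrix: ExpressionMatrix, config: ImputeConfig) -> ExpressionMatrix:
    """Fill each missing cell (g, s) with the mean of the k nearest proteins'
    values in sample s.

    Neighbours are proteins (rows), since proteomics matrices have far more
    proteins than samples.  Distance is Euclidean over jointly observed
    samples, rescaled by the overlap so sparsity does not shrink distances.
    Neighbours missing sample s are skipped in favour of the next nearest;
    a protein with no usable neighbour falls back to its own row mean.
    """
    _require_logged(matrix)
    values = matrix.values.copy()
    mask = np.isnan(values)
    n_prot, n_samp = values.shape
    if config.k >= n_prot:
        raise CombistatError(f"k={config.k} must be < n_proteins={n_prot}")
    if not mask.any():
        return matrix.copy()

    filled = np.nan_to_num(values, nan=0.0)
    obs = (~mask).astype(float)
    # overlap-scaled squared distances: mean squared difference over jointly
    # observed samples, times the number of samples
    sq = filled ** 2
    rows_with_missing = np.where(mask.any(axis=1))[0]
    row_means = np.where((~mask).any(axis=1),
                         np.nansum(values, axis=1) / np.maximum((~mask).sum(axis=1), 1),
                         np.nan)

    for g in rows_with_missing:
        overlap = obs @ obs[g]                      # joint observed counts
        diff2 = (sq @ obs[g] + obs @ sq[g]
                 - 2.0 * filled @ (filled[g] * obs[g]))
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.maximum(diff2, 0.0) / overlap * n_samp)
        dist[g] = np.inf
        dist[overlap == 0] = np.inf
        order = np.argsort(dist, kind="stable")
        order = order[np.isfinite(dist[order])]
        for s in np.where(mask[g])[0]:
            donors = order[~mask[order, s]][: config.k]
            if len(donors):
                values[g, s] = values[donors, s].mean()
            elif np.isfinite(row_means[g]):
                values[g, s] = row_means[g]
            else:
                raise CombistatError(
                    f"protein {matrix.protein_ids[g]!r} has no observed values "
                    "and no usable neighbour")
    return matrix.with_values(values)


# -- iterative random forest -------------------------------------------------

def impute_iterative_forest(matrix: ExpressionMatrix, config: ImputeConfig
                            ) -> ExpressionMatrix:
    """missForest-style chained imputation over samples (columns).

    Missing cells start at their protein's row mean.  Each sweep visits the
    samples in increasing missingness order and regresses each on all other
    samples with a random forest fit on the rows where it is observed,
    re-predicting its missing cells.  Sweeps stop at the first increase of the
    normalized squared change in imputed values (or at ``max_iter``); the
    previous iterate is returned.
    """
    _require_logged(matrix)
    values = matrix.values.copy()
    mask = np.isnan(values)
    if not mask.any():
        return matrix.copy()
    n_prot, n_samp = values.shape
    complete_rows = (~mask).all(axis=1).sum()
    if complete_rows < 10:
        raise CombistatError(
            f"iterative_forest needs >=10 complete proteins (found {complete_rows})")

    row_obs = (~mask).sum(axis=1)
    if (row_obs == 0).any():
        bad = matrix.protein_ids[int(np.where(row_obs == 0)[0][0])]
        raise CombistatError(f"protein {bad!r} has no observed values")
    row_means = np.nansum(values, axis=1) / row_obs
    current = values.copy()
    current[mask] = np.take(row_means, np.where(mask)[0])

    col_order = np.argsort(mask.sum(axis=0), kind="stable")
    rng = np.random.default_rng(config.seed)
    prev = current.copy()
    prev_delta = np.inf
    for _ in range(config.max_iter):
        new = current.copy()
        for j in col_order:
            miss_j = mask[:, j]
            if not miss_j.any():
                continue
            others = [c for c in range(n_samp) if c != j]
            rf = RandomForestRegressor(
                n_estimators=config.n_trees,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(new[~miss_j][:, others], new[~miss_j, j])
            new[miss_j, j] = rf.predict(new[miss_j][:, others])
        delta = (np.sum((new[mask] - current[mask]) ** 2)
                 / max(np.sum(new[mask] ** 2), 1e-12))
        if delta >= prev_delta:
            return matrix.with_values(current)
        prev, current, prev_delta = current, new, delta
    return matrix.with_values(current)
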