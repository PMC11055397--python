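"""Seeded spike-in-style simulator for benchmarking the pipeline.

Generates a proteins × samples intensity matrix with known differential
ground truth: per-protein log2 baselines, class-specific spiked effects for a
chosen fraction of proteins, i.i.d. replicate noise, optional batch shifts,
and either completely-random (MCAR) or intensity-dependent left-censored
(MNAR, logistic in log2 intensity) missing values — the missingness regime
that motivates downshifted-normal imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .combinatory import Comparison
from .core_data import (CombistatError, ExpressionMatrix, MetadataTable,
                        SampleMetadata)
from .dea import DEACutoffs, DEAResult

MNAR_SLOPE = 0.5    # logistic slope, log2 units


@dataclass(frozen=True)
class SpikeInConfig:
    n_proteins: int = 2000
    classes: tuple[tuple[str, int], ...] = (("A", 4), ("B", 4), ("C", 4))
    frac_de: float = 0.1
    effect_log2: float | tuple[float, float] = 1.5
    baseline_mean: float = 23.0     # log2 units
    protein_sd: float = 1.5
    noise_sd: float = 0.3
    missing_mode: str = "mnar_logistic"   # none | mcar | mnar_logistic
    missing_rate: float = 0.1
    batch_effects: tuple[tuple[str, float], ...] | None = None  # (batch, log2 shift) per class-block
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.frac_de <= 1):
            raise CombistatError("frac_de must be in [0, 1]")
        if self.protein_sd <= 0 or self.noise_sd <= 0:
            raise CombistatError("SDs must be > 0")
        if any(n < 2 for _, n in self.classes):
            raise CombistatError("every class needs >=2 replicates")
        if self.missing_mode not in ("none", "mcar", "mnar_logistic"):
            raise CombistatError(f"unknown missing_mode {self.missing_mode!r}")
        if self.missing_mode != "none" and self.missing_rate > 0.9:
            raise CombistatError("missing_rate > 0.9 is infeasible")


@dataclass
class SpikeInTruth:
    """Ground truth: protein -> (affected class, signed log2 effect)."""

    de_proteins: dict[str, tuple[str, float]]
    missing_truth: np.ndarray    # boolean mask of generated holes

    def expected_logfc(self, comparison: Comparison, protein_id: str) -> float:
        """Expected log2 contrast (group_a mean − group_b mean) under truth."""
        cls, eff = self.de_proteins.get(protein_id, (None, 0.0))
        if cls is None:
            return 0.0
        a, b = comparison.group_a, comparison.group_b
        if cls in a:
            return eff / len(a)
        if cls in b:
            return -eff / len(b)
        return 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"protein": p, "affected_class": c, "effect_log2": e}
                for p, (c, e) in sorted(self.de_proteins.items())]
        return pd.DataFrame(rows, columns=["protein", "affected_class", "effect_log2"])


def generate(config: SpikeInConfig
             ) -> tuple[ExpressionMatrix, MetadataTable, SpikeInTruth]:
    """Simulate (matrix, metadata, truth); the matrix is raw-scale with holes.

    Per protein g: baseline b_g ~ Normal(baseline_mean, protein_sd²); sample s
    of class c gets b_g + Δ_gc + Normal(0, noise_sd²) on the log2 scale, where
    Δ_gc is the spiked effect for differential proteins in their affected
    class and 0 otherwise.  MNAR holes are punched with probability
    1/(1 + exp((x − τ)/0.5)), τ calibrated so the overall missing fraction
    matches ``missing_rate``.  Bit-identical for identical seeds.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    protein_ids = [f"P{i + 1:05d}" for i in range(n)]

    sample_ids, class_labels = [], []
    batch_shift = dict(config.batch_effects) if config.batch_effects else {}
    for cls, reps in config.classes:
        for r in range(reps):
            sample_ids.append(f"{cls}{r + 1}")
            class_labels.append(cls)
    meta = MetadataTable([
        SampleMetadata(s, c, batch=(c if batch_shift else None))
        for s, c in zip(sample_ids, class_labels)
    ])

    baselines = rng.normal(config.baseline_mean, config.protein_sd, size=n)

    n_de = round(config.frac_de * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    class_names = [c for c, _ in config.classes]
    affected = rng.choice(len(class_names), size=n_de)
    if isinstance(config.effect_log2, tuple):
        lo, hi = config.effect_log2
        effects = rng.uniform(lo, hi, size=n_de)
    else:
        effects = np.full(n_de, float(config.effect_log2))

    delta = np.zeros((n, len(sample_ids)))
    col_class = np.array(class_labels)
    for i, g in enumerate(de_idx):
        delta[g, col_class == class_names[affected[i]]] = effects[i]

    log2_values = (baselines[:, None] + delta
                   + rng.normal(0.0, config.noise_sd, size=delta.shape))
    if batch_shift:
        for j, cls in enumerate(class_labels):
            log2_values[:, j] += batch_shift.get(cls, 0.0)

    holes = np.zeros_like(log2_values, dtype=bool)
    if config.missing_mode == "mcar" and config.missing_rate > 0:
        holes = rng.random(log2_values.shape) < config.missing_rate
    elif config.missing_mode == "mnar_logistic" and config.missing_rate > 0:
        x = log2_values.ravel()

        def mean_prob(tau: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp((x - tau) / MNAR_SLOPE))))

        lo_t, hi_t = x.min() - 10, x.max() + 10
        tau = optimize.brentq(lambda t: mean_prob(t) - config.missing_rate,
                              lo_t, hi_t, xtol=1e-9)
        prob = 1.0 / (1.0 + np.exp((log2_values - tau) / MNAR_SLOPE))
        holes = rng.random(log2_values.shape) < prob

    raw = np.power(2.0, log2_values)
    raw[holes] = np.nan
    matrix = ExpressionMatrix(
        pd.DataFrame(raw, index=protein_ids, columns=sample_ids), "raw")
    truth = SpikeInTruth(
        de_proteins={protein_ids[g]: (class_names[affected[i]], float(effects[i]))
                     for i, g in enumerate(de_idx)},
        missing_truth=holes,
    )
    return matrix, meta, truth


@dataclass
class ConfusionSummary:
    sensitivity: float
    fdr: float
    specificity: float
    tp: int
    fp: int
    fn: int
    tn: int
    fdr_undefined: bool = False


def truth_confusion(result: DEAResult, truth: SpikeInTruth,
                    cutoffs: DEACutoffs) -> ConfusionSummary:
    """Confusion counts of the significant set against ground truth.

    A protein counts as a true positive candidate when the magnitude of its
    expected contrast under the truth reaches the fold-change call cutoff —
    for a single-class pair that is exactly the spiked proteins affected in
    either class.
    """
    called = set(result.significant_ids)
    table_ids = set(result.table["protein"])
    unknown = {p for p, _ in truth.de_proteins.items()} - table_ids
    if unknown:
        raise CombistatError(
            f"truth contains proteins absent from the result: {sorted(unknown)[:5]}")
    tp = fp = fn = tn = 0
    for pid in result.table["protein"]:
        is_pos = abs(truth.expected_logfc(result.comparison, pid)) \
            >= cutoffs.min_abs_logfc
        if pid in called:
            tp += is_pos
            fp += not is_pos
        else:
            fn += is_pos
            tn += not is_pos
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    fdr_undef = (tp + fp) == 0
    fdr = 0.0 if fdr_undef else fp / (tp + fp)
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    return ConfusionSummary(sens, fdr, spec, tp, fp, fn, tn, fdr_undef)


def write_simulation(matrix: ExpressionMatrix, meta: MetadataTable,
                     truth: SpikeInTruth, out_dir: str | Path) -> None:
    from .core_data import write_expression_csv, write_metadata_csv
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_expression_csv(matrix, out_dir / "matrix.csv")
    write_metadata_csv(meta, out_dir / "meta.csv")
    truth.to_frame().to_csv(out_dir / "truth.csv", index=False)
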