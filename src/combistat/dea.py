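"""Per-protein two-group linear modelling with empirical-Bayes moderated
t-statistics, Benjamini–Hochberg correction and cutoff filtering.

The model follows the standard moderated-t construction: per protein g the
contrast estimate is the group-mean difference (log2 fold change), the
residual variance s²_g has d = n_a + n_b − 2 degrees of freedom, and the
variances are shrunk toward a prior s0² with prior degrees of freedom d0
estimated across all proteins by a method-of-moments fit on log s²:

    s̃²_g = (d0·s0² + d·s²_g) / (d0 + d)
    t_g   = logFC_g / sqrt(s̃²_g · (1/n_a + 1/n_b))

with p-values from a Student t on d + d0 degrees of freedom (normal tail when
d0 hits the infinity cap).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .combinatory import Comparison, ComparisonPlan
from .core_data import (LOG2, LOG10, CombistatError, ExpressionMatrix,
                        MetadataTable, align_metadata)

D0_CAP = 1e6            # prior df at/above this are treated as infinite
VAR_FLOOR = 1e-8        # floor for zero residual variances
_LOG10_TO_LOG2 = np.log2(10.0)


@dataclass(frozen=True)
class DEACutoffs:
    min_abs_logfc: float = 1.0   # log2 units
    max_adj_p: float = 0.05

    def __post_init__(self):
        if self.min_abs_logfc < 0:
            raise CombistatError("min_abs_logfc must be >= 0")
        if not (0 < self.max_adj_p <= 1):
            raise CombistatError("max_adj_p must be in (0, 1]")


@dataclass
class GroupFit:
    """Per-protein contrast estimates before moderation."""

    protein_ids: list[str]
    logfc: np.ndarray        # log2 units
    s2: np.ndarray           # pooled within-group variance (log2 scale)
    d: int                   # residual df, n_a + n_b − 2
    v_c: float               # unscaled SE factor 1/n_a + 1/n_b
    n_a: int
    n_b: int


@dataclass
class DEAResult:
    comparison: Comparison
    table: pd.DataFrame      # sorted by P: protein, logFC, t, P, adjP, significant, direction
    d0: float
    s0_sq: float
    cutoffs: DEACutoffs

    @property
    def significant_ids(self) -> list[str]:
        return self.table.loc[self.table["significant"], "protein"].tolist()


# -- two-group fit -----------------------------------------------------------

def fit_two_group(matrix: ExpressionMatrix, meta: MetadataTable,
                  comparison: Comparison) -> GroupFit:
    """Group-mean contrast and pooled variance for every protein.

    Grouped comparisons pool their member classes into a single cell (the
    cell-means design with one contrast).  Requires a complete,
    log-transformed matrix; log10 inputs are converted so logFC is always in
    log2 units.
    """
    if matrix.scale_tag not in (LOG2, LOG10):
        raise CombistatError("DEA expects a log-transformed matrix")
    if np.isnan(matrix.values).any():
        raise CombistatError(
            "matrix contains missing values; run imputation first")
    meta = align_metadata(matrix, meta)
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    a_cols = [col[s] for s in meta.samples_in_classes(comparison.group_a)]
    b_cols = [col[s] for s in meta.samples_in_classes(comparison.group_b)]
    n_a, n_b = len(a_cols), len(b_cols)
    if n_a < 2 or n_b < 2:
        raise CombistatError(
            f"comparison {comparison.name}: each group needs >=2 samples "
            f"(got {n_a} vs {n_b})")
    values = matrix.values
    if matrix.scale_tag == LOG10:
        values = values * _LOG10_TO_LOG2
    A = values[:, a_cols]
    B = values[:, b_cols]
    logfc = A.mean(axis=1) - B.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    d = n_a + n_b - 2
    s2 = ss / d
    return GroupFit(matrix.protein_ids, logfc, s2, d, 1.0 / n_a + 1.0 / n_b,
                    n_a, n_b)


# -- empirical Bayes hyperparameters ----------------------------------------

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is monotone decreasing)."""
    if y <= 0:
        raise CombistatError("trigamma_inverse needs y > 0")
    lo, hi = 1e-8, 1e8
    if special.polygamma(1, lo) < y:
        return lo
    if special.polygamma(1, hi) > y:
        return hi
    return float(optimize.brentq(lambda x: special.polygamma(1, x) - y,
                                 lo, hi, xtol=1e-12, rtol=1e-14))


def estimate_prior(s2: np.ndarray, d: int, *, eps: float = 1e-12
                   ) -> tuple[float, float]:
    """Method-of-moments fit of the prior df d0 and prior variance s0².

    Under the hierarchical model s²_g | σ²_g ~ σ²_g·χ²_d/d with
    σ²_g ~ s0²·d0/χ²_{d0}, the log residual variances e_g = log s²_g satisfy
    Var[e] = trigamma(d/2) + trigamma(d0/2), so d0 comes from inverting the
    trigamma at the excess dispersion of e, and

        log s0² = mean(e) − digamma(d/2) + digamma(d0/2) + log(d/d0).

    When there is no excess dispersion d0 is infinite (capped at 1e6).
    Zero/negative variances are floored at 1e-8 before taking logs.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if len(s2) < 10:
        raise CombistatError(
            f"prior estimation needs >=10 finite variances (got {len(s2)})")
    s2 = np.maximum(s2, VAR_FLOOR)
    e = np.log(s2)
    g = len(e)
    excess = e.var(ddof=0) * g / (g - 1) - special.polygamma(1, d / 2.0)
    if excess <= eps:
        d0 = D0_CAP
        s0_sq = float(np.exp(e.mean() - special.polygamma(0, d / 2.0)
                             + np.log(d / 2.0)))
        return d0, s0_sq
    d0 = 2.0 * trigamma_inverse(float(excess))
    d0 = min(d0, D0_CAP)
    s0_sq = float(np.exp(e.mean() - special.polygamma(0, d / 2.0)
                         + special.polygamma(0, d0 / 2.0) + np.log(d / d0)))
    return float(d0), s0_sq


# -- moderation and testing --------------------------------------------------

def moderate(fit: GroupFit, d0: float, s0_sq: float) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values.

    d0 = 0 gives the ordinary pooled two-sample t; d0 at the cap gives a
    normal reference with every variance shrunk fully to s0².
    """
    if d0 < 0 or s0_sq < 0:
        raise CombistatError("d0 and s0_sq must be non-negative")
    if d0 >= D0_CAP:
        s2_post = np.full_like(fit.s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + fit.d * fit.s2) / (d0 + fit.d)
        df_total = fit.d + d0
    se = np.sqrt(s2_post * fit.v_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fit.logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame({
        "protein": fit.protein_ids,
        "logFC": fit.logfc,
        "s2": fit.s2,
        "s2_post": s2_post,
        "t": t,
        "P": p,
    })


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j>=i} m·p_(j)/j, clipped at 1, mapped back to input order.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise CombistatError("p-values must be finite and in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def filter_deps(table: pd.DataFrame, comparison: Comparison, d0: float,
                s0_sq: float, cutoffs: DEACutoffs) -> DEAResult:
    """Adjust p-values, call significance and sort the result table.

    A protein is significant iff |logFC| >= min_abs_logfc and adjusted
    P <= max_adj_p; direction "up" means higher in group_a.  Rows are sorted
    by P ascending, ties by |logFC| descending then protein id.
    """
    tab = table.copy()
    tab["adjP"] = bh_adjust(tab["P"].to_numpy())
    tab["significant"] = ((tab["logFC"].abs() >= cutoffs.min_abs_logfc)
                          & (tab["adjP"] <= cutoffs.max_adj_p))
    tab["direction"] = np.where(~tab["significant"], "ns",
                                np.where(tab["logFC"] > 0, "up", "down"))
    tab = tab.sort_values(
        by=["P", "logFC", "protein"],
        ascending=[True, False, True],
        key=lambda col: col.abs() if col.name == "logFC" else col,
        kind="stable",
    ).reset_index(drop=True)
    return DEAResult(comparison, tab, d0, s0_sq, cutoffs)


def run_comparison(matrix: ExpressionMatrix, meta: MetadataTable,
                   comparison: Comparison,
                   cutoffs: DEACutoffs = DEACutoffs()) -> DEAResult:
    """Fit, moderate, adjust and filter one comparison end to end."""
    fit = fit_two_group(matrix, meta, comparison)
    d0, s0_sq = estimate_prior(fit.s2, fit.d)
    table = moderate(fit, d0, s0_sq)
    return filter_deps(table, comparison, d0, s0_sq, cutoffs)


@dataclass
class PlanRun:
    results: list[DEAResult]
    errors: dict[str, str]       # comparison name -> message

    def index_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "comparison": r.comparison.name,
                "n_a": "+".join(r.comparison.group_a),
                "n_b": (r.comparison.b_label or "+".join(r.comparison.group_b)),
                "n_significant": int(r.table["significant"].sum()),
                "d0": r.d0,
                "s0_sq": r.s0_sq,
            })
        return pd.DataFrame(rows)


def run_plan(matrix: ExpressionMatrix, meta: MetadataTable,
             plan: ComparisonPlan,
             cutoffs: DEACutoffs = DEACutoffs()) -> PlanRun:
    """Run every comparison of a plan independently, in plan order.

    Empirical-Bayes hyperparameters are re-fit per comparison on its own
    sample subset.  A comparison failing its preconditions is recorded as an
    error; the remaining comparisons still run.
    """
    if len(plan) == 0:
        raise CombistatError("empty comparison plan")
    results, errors = [], {}
    for comp in plan:
        try:
            results.append(run_comparison(matrix, meta, comp, cutoffs))
        except CombistatError as exc:
            errors[comp.name] = str(exc)
    return PlanRun(results, errors)


# -- export ------------------------------------------------------------------

def export_results(run: PlanRun, out_dir: str | Path, *,
                   xlsx: bool = False) -> list[Path]:
    """One CSV per comparison plus an index table; optionally a single
    multi-sheet workbook with one sheet per comparison."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    cols = ["protein", "logFC", "t", "P", "adjP", "significant", "direction"]
    for r in run.results:
        path = out_dir / f"{r.comparison.name}.csv"
        r.table[cols].to_csv(path, index=False)
        written.append(path)
    idx_path = out_dir / "index.csv"
    run.index_frame().to_csv(idx_path, index=False)
    written.append(idx_path)
    if xlsx:
        xlsx_path = out_dir / "results.xlsx"
        with pd.ExcelWriter(xlsx_path, engine="openpyxl") as writer:
            run.index_frame().to_excel(writer, sheet_name="index", index=False)
            for r in run.results:
                sheet = r.comparison.name[:31]   # sheet-name length limit
                r.table[cols].to_excel(writer, sheet_name=sheet, index=False)
        written.append(xlsx_path)
    return written
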