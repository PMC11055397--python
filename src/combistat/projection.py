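"""Analysis-ready tables for visualization: PCA over samples, volcano tables,
top-DEP expression extracts, hierarchical-clustering leaf orders, and static
plot rendering — plus PCA restricted to a functional protein class (protease
/ kinase / transcription-factor lists or any user-supplied identifier list).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import pdist

from .core_data import CombistatError, ExpressionMatrix, MetadataTable, align_metadata
from .dea import DEACutoffs, DEAResult


@dataclass
class PCAResult:
    scores: pd.DataFrame              # samples × k
    loadings: pd.DataFrame            # proteins × k
    variance_explained: np.ndarray    # k fractions, non-increasing
    n_matched: int | None = None      # subset analyses: matched protein count
    n_unmatched: int | None = None


@dataclass(frozen=True)
class ProteinClassList:
    """Named set of protein identifiers (uppercased for matching)."""

    class_name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise CombistatError("protein class list is empty")
        object.__setattr__(self, "members",
                           frozenset(m.upper() for m in self.members))


def read_class_list(path: str | Path, class_name: str = "custom") -> ProteinClassList:
    """Plain text, one identifier per line, ``#`` comments allowed."""
    members = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            members.append(line)
    return ProteinClassList(class_name, frozenset(members))


# -- PCA ---------------------------------------------------------------------

def pca(matrix: ExpressionMatrix, k: int | None = None, *,
        scale: bool = False) -> PCAResult:
    """PCA of samples over protein features via SVD.

    Each protein is centered across samples (unit-variance scaling optional);
    sign convention: the largest-magnitude loading of each component is
    positive.
    """
    values = matrix.values
    if np.isnan(values).any():
        raise CombistatError("PCA needs a complete matrix; run imputation first")
    n_prot, n_samp = values.shape
    max_k = min(n_prot, n_samp)
    if k is None:
        k = min(max_k, 10)
    if not (1 <= k <= max_k):
        raise CombistatError(f"k must be in [1, {max_k}]")
    X = values.T - values.mean(axis=1)           # samples × proteins, centered
    if scale:
        sd = values.std(axis=1, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((S ** 2).sum())
    var_exp = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=pcs),
        loadings=pd.DataFrame(loadings, index=matrix.protein_ids, columns=pcs),
        variance_explained=var_exp,
    )


def subset_pca(matrix: ExpressionMatrix, class_list: ProteinClassList,
               k: int | None = None, *, scale: bool = False) -> PCAResult:
    """PCA restricted to the proteins in a functional class list."""
    upper = {p.upper(): p for p in matrix.protein_ids}
    matched = [upper[m] for m in sorted(class_list.members) if m in upper]
    n_unmatched = len(class_list.members) - len(matched)
    if len(matched) < 3:
        raise CombistatError(
            f"class {class_list.class_name!r} matches only {len(matched)} "
            "proteins (need >=3)")
    sub = ExpressionMatrix(matrix.data.loc[matched], matrix.scale_tag)
    res = pca(sub, k, scale=scale)
    res.n_matched = len(matched)
    res.n_unmatched = n_unmatched
    return res


# -- DEA-derived tables ------------------------------------------------------

def volcano_table(result: DEAResult, cutoffs: DEACutoffs | None = None) -> pd.DataFrame:
    """Per protein: logFC, −log10(adjP) and category up/down/ns."""
    cutoffs = cutoffs or result.cutoffs
    tab = result.table
    with np.errstate(divide="ignore"):
        neg_log = -np.log10(np.maximum(tab["adjP"].to_numpy(), 1e-300))
    sig = ((tab["logFC"].abs() >= cutoffs.min_abs_logfc)
           & (tab["adjP"] <= cutoffs.max_adj_p))
    category = np.where(~sig, "ns", np.where(tab["logFC"] > 0, "up", "down"))
    return pd.DataFrame({
        "protein": tab["protein"],
        "logFC": tab["logFC"],
        "neg_log10_adjP": neg_log,
        "category": category,
    })


def top_dep_expression(result: DEAResult, matrix: ExpressionMatrix,
                       meta: MetadataTable, n_top: int = 50,
                       direction: str | None = None
                       ) -> tuple[pd.DataFrame, str | None]:
    """Long-format expression of the most significant DEPs.

    ``direction`` restricts to "up" or "down" regulated proteins.  Returns
    (table, note); the note reports when fewer DEPs than requested exist.
    """
    if n_top < 1:
        raise CombistatError("n_top must be >= 1")
    meta = align_metadata(matrix, meta)
    tab = result.table[result.table["significant"]]
    if direction in ("up", "down"):
        tab = tab[tab["direction"] == direction]
    elif direction is not None:
        raise CombistatError("direction must be 'up', 'down' or None")
    proteins = tab["protein"].head(n_top).tolist()
    note = None
    if len(proteins) < n_top:
        note = (f"only {len(proteins)} significant protein(s) available "
                f"(requested {n_top})")
    rows = []
    for pid in proteins:
        for sid in matrix.sample_ids:
            rows.append({"protein": pid, "sample": sid,
                         "class": meta.class_of(sid),
                         "value": matrix.data.at[pid, sid]})
    cols = ["protein", "sample", "class", "value"]
    return pd.DataFrame(rows, columns=cols), note


# -- hierarchical clustering -------------------------------------------------

@dataclass
class HeatmapOrder:
    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def heatmap_order(matrix: ExpressionMatrix, distance: str = "euclidean",
                  linkage_method: str = "average") -> HeatmapOrder:
    """Row and column leaf orders from agglomerative clustering
    (defaults: Euclidean distance, average linkage)."""
    values = matrix.values
    if not np.isfinite(values).all():
        raise CombistatError("heatmap clustering needs a complete finite matrix")

    def _order(data: np.ndarray) -> tuple[list[int], np.ndarray]:
        if data.shape[0] < 2:
            return list(range(data.shape[0])), np.empty((0, 4))
        Z = linkage(pdist(data, metric=distance), method=linkage_method)
        leaves = dendrogram(Z, no_plot=True)["leaves"]
        return list(leaves), Z

    row_order, row_z = _order(values)
    col_order, col_z = _order(values.T)
    return HeatmapOrder(row_order, col_order, row_z, col_z)


# -- gene-list export --------------------------------------------------------

def export_gene_lists(result: DEAResult, out_dir: str | Path) -> list[Path]:
    """Ranked significant-protein lists (CSV + newline-delimited symbols)
    formatted for pasting into DAVID / ShinyGO / STRING."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig = result.table[result.table["significant"]]
    base = result.comparison.name
    csv_path = out_dir / f"{base}_gene_list.csv"
    sig[["protein", "logFC", "adjP", "direction"]].to_csv(csv_path, index=False)
    txt_path = out_dir / f"{base}_gene_list.txt"
    txt_path.write_text("\n".join(sig["protein"].tolist()) + "\n")
    return [csv_path, txt_path]


# -- static rendering --------------------------------------------------------

def render_plots(matrix: ExpressionMatrix, meta: MetadataTable,
                 result: DEAResult, out_dir: str | Path,
                 n_top: int = 50) -> list[Path]:
    """Write static volcano / PCA / top-DEP boxplot / heatmap images, each
    with its underlying CSV table alongside.

    Rendering failures degrade to table-only output with a warning.
    """
    import warnings

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = align_metadata(matrix, meta)
    written: list[Path] = []

    def _save(fig, name: str):
        path = out_dir / name
        try:
            fig.savefig(path, dpi=120)
            written.append(path)
        except Exception as exc:   # pragma: no cover - rendering environment
            warnings.warn(f"could not render {name}: {exc}")
        finally:
            plt.close(fig)

    # volcano
    volcano = volcano_table(result)
    volcano.to_csv(out_dir / "volcano.csv", index=False)
    written.append(out_dir / "volcano.csv")
    fig, ax = plt.subplots(figsize=(5, 4))
    palette = {"up": "#d62728", "down": "#1f77b4", "ns": "#bbbbbb"}
    for cat, sub in volcano.groupby("category"):
        ax.scatter(sub["logFC"], sub["neg_log10_adjP"], s=6,
                   c=palette.get(cat, "black"), label=cat)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted P")
    ax.set_title(result.comparison.name)
    ax.legend(frameon=False, fontsize=8)
    _save(fig, "volcano.png")

    # PCA colored by class
    pca_res = pca(matrix, k=2)
    scores = pca_res.scores.copy()
    scores["class"] = [meta.class_of(s) for s in scores.index]
    scores.to_csv(out_dir / "pca_scores.csv")
    written.append(out_dir / "pca_scores.csv")
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, sub in scores.groupby("class"):
        ax.scatter(sub["PC1"], sub["PC2"], label=cls, s=25)
    ax.set_xlabel(f"PC1 ({pca_res.variance_explained[0]:.1%})")
    ax.set_ylabel(f"PC2 ({pca_res.variance_explained[1]:.1%})"
                  if len(pca_res.variance_explained) > 1 else "PC2")
    ax.legend(frameon=False, fontsize=8)
    _save(fig, "pca.png")

    # top-DEP boxplots
    top, _note = top_dep_expression(result, matrix, meta, n_top=n_top)
    top.to_csv(out_dir / "top_deps.csv", index=False)
    written.append(out_dir / "top_deps.csv")
    fig, ax = plt.subplots(figsize=(6, 4))
    if not top.empty:
        classes = sorted(top["class"].unique())
        data = [top.loc[top["class"] == c, "value"].dropna() for c in classes]
        ax.boxplot(data, tick_labels=classes)
        ax.set_ylabel("abundance")
        ax.set_title(f"top {top['protein'].nunique()} DEPs")
    _save(fig, "top_deps_boxplot.png")

    # heatmap of top DEPs (falls back to full matrix when no DEPs)
    sig_ids = result.significant_ids[:n_top] or matrix.protein_ids[:n_top]
    sub = ExpressionMatrix(matrix.data.loc[sig_ids], matrix.scale_tag)
    order = heatmap_order(sub)
    hm = sub.data.iloc[order.row_order, order.col_order]
    hm.to_csv(out_dir / "heatmap.csv")
    written.append(out_dir / "heatmap.csv")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(hm.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(hm.shape[1]))
    ax.set_xticklabels(hm.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.7)
    _save(fig, "heatmap.png")

    return written
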