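"""Probabilistic SNP annotations from specifically expressed genes.

Pipeline: normalize a labeled cell x gene count matrix to log2(TP10K + 1);
score each gene's specific expression in each cell type by a one-sided
Wilcoxon rank-sum test (focal cells vs. all other brain cells) and min-max
normalize -2*log(p) across genes into a [0, 1] score; then transfer gene
scores to SNPs through enhancer-gene links (or a gene-body +/- 100 kb
window), assigning every SNP the maximum score among its linked genes and 0
when no gene is linked. The union of links over all analyzed genes is the
binary background annotation.

Expression travels as an :class:`anndata.AnnData` (cells x genes) with a
cell-type label column in ``.obs``; MatrixMarket triplets are read through
:func:`read_expression`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy import stats

from .io import Annotation, Intervals, SnpPanel

logger = logging.getLogger("h2scan")

__all__ = [
    "read_expression",
    "normalize_expression",
    "GeneScoreMatrix",
    "rank_sum_pvalues",
    "specific_expression_scores",
    "link_snps",
    "windows_from_genes",
    "union_links_background",
    "binarize_annotation",
]

LABEL_KEY = "cell_type"
WINDOW_BP = 100_000


def read_expression(
    mtx: str | Path,
    cells_tsv: str | Path,
    genes_tsv: str | Path,
    label_column: str = LABEL_KEY,
) -> ad.AnnData:
    """Load a MatrixMarket counts triplet into an AnnData (cells x genes).

    ``cells_tsv`` must carry one row per cell with at least the cell-type
    label column; ``genes_tsv`` one row per gene with a ``gene`` column.
    The matrix is cells x genes (transposed automatically if needed).
    """
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx)))
    obs = pd.read_csv(cells_tsv, sep="\t")
    var = pd.read_csv(genes_tsv, sep="\t")
    if counts.shape != (len(obs), len(var)):
        if counts.shape == (len(var), len(obs)):
            counts = counts.T.tocsr()
        else:
            raise ValueError("matrix shape matches neither cells x genes nor its transpose")
    if label_column not in obs.columns:
        raise ValueError(f"cell metadata lacks label column {label_column!r}")
    obs.index = obs.index.astype(str)
    var.index = var["gene"].astype(str)
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.obs[LABEL_KEY] = adata.obs[label_column].astype(str).values
    return adata


def normalize_expression(adata: ad.AnnData) -> ad.AnnData:
    """Transform counts to log2(TP10K + 1); zero-total cells are dropped."""
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} cells with zero total counts")
        adata = adata[keep].copy()
        X = adata.X
        totals = totals[keep]
    if sp.issparse(X):
        norm = X.multiply(1e4 / totals[:, None]).tocsr()
        norm.data = np.log2(norm.data + 1.0)
    else:
        norm = np.log2(1e4 * np.asarray(X) / totals[:, None] + 1.0)
    out = adata.copy()
    out.X = norm
    out.obs["total_counts"] = totals
    return out


@dataclass
class GeneScoreMatrix:
    """Specific-expression scores (genes x cell types, in [0, 1]) and the
    underlying one-sided rank-sum p-values."""

    scores: pd.DataFrame
    pvalues: pd.DataFrame

    @property
    def celltypes(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def genes(self) -> pd.Index:
        return self.scores.index


def _tie_term(col: np.ndarray) -> float:
    _, counts = np.unique(col, return_counts=True)
    return float((counts**3 - counts).sum())


def rank_sum_pvalues(
    X: np.ndarray,
    labels: np.ndarray,
    alternative: str = "greater",
    exact_max: int = 10,
) -> pd.DataFrame:
    """One-sided rank-sum p-values of every gene in every cell type.

    Mid-rank normal approximation with tie-corrected variance and continuity
    correction, computed from a single ranking per gene shared across cell
    types. Groups where both sides have <= ``exact_max`` cells and the gene
    has no ties use the exact Mann-Whitney distribution instead.
    """
    X = np.asarray(X, dtype=float)
    n_cells, n_genes = X.shape
    cts = pd.unique(labels)
    if len(cts) < 2:
        raise ValueError("need at least 2 cell types for specific expression")
    ranks = stats.rankdata(X, axis=0)
    ties = np.array([_tie_term(X[:, g]) for g in range(n_genes)])
    N = float(n_cells)
    out = {}
    for ct in cts:
        mask = labels == ct
        n1 = float(mask.sum())
        n2 = N - n1
        if n1 == 0:
            raise ValueError(f"cell type {ct!r} has no cells")
        R1 = ranks[mask].sum(axis=0)
        U = R1 - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        var = n1 * n2 / 12.0 * ((N + 1) - ties / (N * (N - 1)))
        # continuity correction toward the alternative, as in the classical
        # normal approximation
        with np.errstate(divide="ignore", invalid="ignore"):
            if alternative == "greater":
                z = (U - mu - 0.5) / np.sqrt(var)
            elif alternative == "two-sided":
                z = (np.abs(U - mu) - 0.5) / np.sqrt(var)
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
        z = np.where(var > 0, z, 0.0)
        if alternative == "greater":
            p = stats.norm.sf(z)
        else:
            p = np.minimum(2 * stats.norm.sf(z), 1.0)
        p = np.where(var > 0, p, 1.0)
        if n1 <= exact_max and n2 <= exact_max:
            for g in np.flatnonzero(ties == 0):
                p[g] = stats.mannwhitneyu(
                    X[mask, g], X[~mask, g], alternative=alternative, method="exact"
                ).pvalue
        out[ct] = p
    return pd.DataFrame(out)


def specific_expression_scores(
    adata: ad.AnnData,
    label_key: str = LABEL_KEY,
    alternative: str = "greater",
    gene_min_cells: int = 10,
) -> GeneScoreMatrix:
    """Min-max-normalized -2*log(p) specific-expression scores per cell type.

    The gene universe is restricted to genes expressed in at least
    ``gene_min_cells`` cells. Within each cell type, the gene with the
    smallest p-value scores 1 and the largest scores 0; if every gene has
    the same p-value the cell type's scores are all set to 0 (no gene is
    specifically expressed) with a warning.
    """
    X = adata.X
    dense = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    expressed = (dense > 0).sum(axis=0)
    universe = expressed >= gene_min_cells
    if not universe.any():
        raise ValueError("no genes pass the expressed-cell threshold")
    labels = adata.obs[label_key].to_numpy()
    pv = rank_sum_pvalues(dense[:, universe], labels, alternative=alternative)
    pv.index = adata.var_names[universe]
    neg2logp = -2.0 * np.log(np.clip(pv.to_numpy(), 1e-300, None))
    scores = np.zeros_like(neg2logp)
    for j, ct in enumerate(pv.columns):
        col = neg2logp[:, j]
        lo, hi = col.min(), col.max()
        if hi > lo:
            scores[:, j] = (col - lo) / (hi - lo)
        else:
            warnings.warn(f"all rank-sum p equal in cell type {ct!r}; scores set to 0")
    return GeneScoreMatrix(
        scores=pd.DataFrame(scores, index=pv.index, columns=pv.columns),
        pvalues=pv,
    )


def windows_from_genes(genes: pd.DataFrame, window_bp: int = WINDOW_BP) -> Intervals:
    """Gene-body +/- window intervals (0-based half-open, clipped at 0).

    ``genes`` columns: gene, chrom, start, end (0-based half-open bodies).
    """
    t = genes.copy()
    t["start"] = np.clip(t["start"].to_numpy() - window_bp, 0, None)
    t["end"] = t["end"].to_numpy() + window_bp
    return Intervals(t[["chrom", "start", "end", "gene"]])


def _gene_intervals(
    scores: GeneScoreMatrix,
    links: Intervals | None,
    genes: pd.DataFrame | None,
    strategy: str,
) -> pd.DataFrame:
    if strategy == "enhancer_links":
        if links is None:
            raise ValueError("enhancer_links strategy requires a link set")
        ivals = links.table
    elif strategy == "window_100kb":
        if genes is None:
            raise ValueError("window strategy requires gene body coordinates")
        ivals = windows_from_genes(genes).table
    else:
        raise ValueError(f"unknown linking strategy {strategy!r}")
    known = ivals["gene"].isin(scores.genes)
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.info("ignoring %d link intervals for genes without scores", n_unknown)
    return ivals.loc[known].reset_index(drop=True)


def _snp_gene_max(
    ivals: pd.DataFrame, panel: SnpPanel, gene_value: pd.Series
) -> np.ndarray:
    """Per-SNP maximum of gene_value over genes whose interval contains the SNP."""
    values = np.zeros(panel.M)
    snps = panel.snps
    vals = gene_value.reindex(ivals["gene"]).to_numpy()
    for chrom, grp in ivals.assign(v=vals).groupby("chrom", sort=False):
        mask = (snps["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos0 = snps.loc[mask, "pos"].to_numpy() - 1
        offset = np.flatnonzero(mask)[0]
        for s, e, v in zip(grp["start"], grp["end"], grp["v"]):
            i0, i1 = np.searchsorted(pos0, [s, e], side="left")
            if i1 > i0:
                sl = slice(offset + i0, offset + i1)
                values[sl] = np.maximum(values[sl], v)
    return values


def link_snps(
    scores: GeneScoreMatrix,
    panel: SnpPanel,
    links: Intervals | None = None,
    genes: pd.DataFrame | None = None,
    strategy: str = "enhancer_links",
) -> list[Annotation]:
    """One probabilistic annotation per cell type.

    A SNP's value is the maximum specific-expression score among genes it is
    linked to (enhancer-gene link intervals, or gene body +/- 100 kb under
    the window strategy), and 0 when no gene is linked.
    """
    ivals = _gene_intervals(scores, links, genes, strategy)
    out = []
    for ct in scores.celltypes:
        vals = _snp_gene_max(ivals, panel, scores.scores[ct])
        out.append(Annotation(name=ct, values=vals, kind="probabilistic", role="celltype"))
    return out


def union_links_background(
    scores: GeneScoreMatrix,
    panel: SnpPanel,
    links: Intervals | None = None,
    genes: pd.DataFrame | None = None,
    strategy: str = "enhancer_links",
) -> Annotation:
    """Binary background: 1 iff the SNP is linked to >= 1 analyzed gene."""
    ivals = _gene_intervals(scores, links, genes, strategy)
    ones = pd.Series(1.0, index=scores.genes)
    vals = _snp_gene_max(ivals, panel, ones)
    return Annotation(name="background", values=vals, kind="binary", role="background")


def binarize_annotation(a: Annotation) -> Annotation:
    """Convert all positive probability scores to 1."""
    return Annotation(
        name=a.name, values=(a.values > 0).astype(float), kind="binary", role=a.role
    )
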