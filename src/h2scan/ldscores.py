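"""Stratified LD scores.

The LD score of regression SNP j with respect to annotation c is

    l(j, c) = sum_k a_ck * r2_jk

over panel SNPs k within a window of j (j itself included), where r_jk is
the genotype correlation. The default estimator applies the finite-panel
bias adjustment r2_adj = r2 - (1 - r2) / (n - 2); the unadjusted estimator
is available for exact oracle comparisons. Windows are centimorgan-based by
default (1 cM radius, the stratified-regression convention) with a kb
fallback; chromosomes are processed independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotationStack, LdScoreTable, SnpPanel

__all__ = ["LdWindow", "pairwise_r2", "ld_scores", "write_ldscores", "read_ldscores"]


@dataclass
class LdWindow:
    """LD window: radius ``size`` in centimorgans (``cm``) or kilobases (``kb``)."""

    mode: str = "cm"
    size: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("cm", "kb"):
            raise ValueError(f"unknown window mode {self.mode!r}")
        if not self.size > 0:
            raise ValueError("window size must be positive")

    def coords(self, panel_snps: pd.DataFrame) -> np.ndarray:
        if self.mode == "cm":
            return panel_snps["cm"].to_numpy(dtype=float)
        return panel_snps["pos"].to_numpy(dtype=float) / 1000.0


def pairwise_r2(panel: SnpPanel, j: int, k: int, adjusted: bool = False) -> float:
    """Squared genotype correlation of panel SNPs j and k.

    With ``adjusted``, returns r2 - (1 - r2) / (n - 2), the unbiased-in-
    expectation estimator for a finite panel of n samples.
    """
    x = panel.standardized()
    n = panel.n_samples
    r = float(x[:, j] @ x[:, k]) / n
    r2 = r * r
    if adjusted:
        r2 = r2 - (1.0 - r2) / (n - 2)
    return r2


def ld_scores(
    panel: SnpPanel,
    stack: AnnotationStack,
    window: LdWindow | None = None,
    regression_snps: set[str] | list[str] | None = None,
    adjusted: bool = True,
    chunk: int = 512,
) -> LdScoreTable:
    """Stratified LD scores of the regression SNPs for every annotation.

    ``regression_snps`` restricts the rows (e.g. a well-imputed SNP list);
    the sum over k always runs over all panel SNPs in the window. Defaults
    to all panel SNPs as regression SNPs.
    """
    window = window or LdWindow()
    A = stack.matrix()
    if A.shape[0] != panel.M:
        raise ValueError("annotation stack length does not match panel")
    if regression_snps is None:
        reg_mask = np.ones(panel.M, dtype=bool)
    else:
        reg_set = set(regression_snps)
        reg_mask = panel.snps["snp_id"].isin(reg_set).to_numpy()
        if not reg_mask.any():
            raise ValueError("empty regression SNP set after intersection with panel")
    x = panel.standardized()
    n = panel.n_samples
    coords = window.coords(panel.snps)
    out = np.zeros((int(reg_mask.sum()), A.shape[1]))
    row = 0
    for _, sl in panel.chrom_slices():
        xc = x[:, sl]
        Ac = A[sl]
        cc = coords[sl]
        reg_idx = np.flatnonzero(reg_mask[sl])
        lo_all = np.searchsorted(cc, cc - window.size, side="left")
        hi_all = np.searchsorted(cc, cc + window.size, side="right")
        for start in range(0, len(reg_idx), chunk):
            idx = reg_idx[start : start + chunk]
            lo, hi = int(lo_all[idx].min()), int(hi_all[idx].max())
            r = (xc[:, idx].T @ xc[:, lo:hi]) / n
            r2 = r * r
            if adjusted:
                r2 = r2 - (1.0 - r2) / (n - 2)
            # zero out pairs outside each SNP's own window
            cols = np.arange(lo, hi)
            in_win = (cols[None, :] >= lo_all[idx][:, None]) & (
                cols[None, :] < hi_all[idx][:, None]
            )
            r2 = np.where(in_win, r2, 0.0)
            out[row : row + len(idx)] = r2 @ Ac[lo:hi]
            row += len(idx)
    snps = panel.snps.loc[reg_mask, ["snp_id", "chrom", "pos"]].reset_index(drop=True)
    table = pd.concat(
        [snps, pd.DataFrame(out, columns=stack.names)], axis=1
    )
    spec = f"{window.size}{window.mode}, {'adjusted' if adjusted else 'unadjusted'} r2"
    return LdScoreTable(table=table, annotation_names=stack.names, window_spec=spec)


def write_ldscores(table: LdScoreTable, path) -> None:
    """TSV with columns SNP, CHR, BP, then one LD-score column per annotation."""
    out = table.table.rename(columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP"})
    out.to_csv(path, sep="\t", index=False)


def read_ldscores(path) -> LdScoreTable:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    df = df.rename(columns={"SNP": "snp_id", "CHR": "chrom", "BP": "pos"})
    names = [c for c in df.columns if c not in ("snp_id", "chrom", "pos")]
    return LdScoreTable(table=df, annotation_names=names)
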