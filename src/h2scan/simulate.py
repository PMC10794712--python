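"""Synthetic inputs with the statistical structure the pipeline assumes.

Every input the analysis consumes can be generated here at desk scale: an
LD-block-structured reference panel, binary/probabilistic annotations, GWAS
summary statistics whose chi-square expectation follows the stratified
heritability model exactly, a labeled cell x gene count matrix with planted
marker genes, and peak/link/gene interval files. One integer seed drives a
named stream per generator, so identical configs give byte-identical
fixtures and each stage can be regenerated independently.

Genotypes default to Gaussian dosages from a per-block factor model
(dosage = 2*maf + sd*latent): within-block pairwise correlation then has
expectation exactly ``within_block_r`` and across-block correlation 0. A
hard-call mode thresholds two latent haplotypes instead; it attenuates the
latent correlation and exists for PLINK-format round trips.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .atac import PeakSet, peaks_to_annotation, union_background
from .io import (
    Annotation,
    AnnotationStack,
    Intervals,
    SnpPanel,
    SumStats,
    write_annot,
    write_intervals,
    write_panel_text,
    write_sumstats,
)
from .ldscores import LdScoreTable, LdWindow, ld_scores

__all__ = [
    "SimConfig",
    "AnnotationSpec",
    "simulate_panel",
    "simulate_annotations",
    "simulate_sumstats",
    "simulate_expression",
    "simulate_intervals",
    "tau_for_tau_star",
    "write_fixture",
]

# named sub-streams so stages can be regenerated independently
_STREAMS = {"panel": 1, "annotations": 2, "sumstats": 3, "expression": 4, "intervals": 5}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream], extra])


@dataclass
class SimConfig:
    """Study conditions for the generators.

    Panel: ``n_snps`` SNPs in LD blocks of ``block_size`` with within-block
    genotype correlation ``within_block_r``; centimorgan positions place one
    block per default LD window. GWAS: marginal z-scores at sample size
    ``gwas_n`` with total baseline heritability ``h2_base`` spread evenly
    over SNPs and a focal cell-type effect sized by ``target_tau_star``.
    Expression: ``n_cells`` cells over ``n_celltypes`` types, ``n_genes``
    genes, ``markers_per_type`` markers boosted ``marker_fold``-fold.
    """

    seed: int = 0
    n_snps: int = 5_000
    n_samples: int = 500
    block_size: int = 20
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    chrom: str = "1"
    bp_spacing: int = 1_000
    cm_block_gap: float = 2.0
    genotype_mode: str = "dosage"  # dosage | hard
    # GWAS
    gwas_n: int = 50_000
    h2_base: float = 0.02
    target_tau_star: float = 1.0
    # expression
    n_cells: int = 1_000
    n_genes: int = 400
    n_celltypes: int = 4
    markers_per_type: int = 10
    marker_fold: float = 8.0
    nb_dispersion: float = 2.0
    # intervals
    peak_coverage: float = 0.1
    peak_halfwidth: int = 50
    n_fixture_celltypes: int = 3
    n_traits: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.within_block_r < 1:
            raise ValueError("within_block_r must be in [0, 1)")
        for name in ("n_snps", "n_samples", "block_size", "gwas_n", "n_cells", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AnnotationSpec:
    name: str
    coverage: float
    kind: str = "binary"
    role: str = "celltype"


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def _block_structure(
    rng: np.random.Generator, m: int, bs: int, r: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block assignment, within-block index, and per-block correlation.

    Block sizes are drawn uniformly in [bs/2, 3bs/2] (mean bs) and the
    per-block correlation uniformly around ``r`` with half-width
    min(r, 1-r, 0.15): real genomes have highly variable local LD, and the
    spread in LD scores this induces is what separates the regression slope
    from its intercept. Pairwise within-block correlation keeps expectation
    ``r``; across blocks it is 0.
    """
    sizes: list[int] = []
    total = 0
    while total < m:
        s = int(rng.integers(max(2, bs // 2), bs + bs // 2 + 1)) if bs > 2 else bs
        sizes.append(s)
        total += s
    sizes_arr = np.array(sizes)
    block_of = np.repeat(np.arange(len(sizes_arr)), sizes_arr)[:m]
    jitter = min(r, 1 - r, 0.15)
    block_r = r + rng.uniform(-jitter, jitter, len(sizes_arr))
    starts = np.concatenate([[0], np.cumsum(sizes_arr)])
    within = np.arange(m) - starts[block_of]
    return block_of, within, block_r


def simulate_panel(cfg: SimConfig) -> SnpPanel:
    """LD-block-structured reference panel.

    SNPs fall into LD blocks of mean size ``block_size``; a shared latent
    factor per (sample, block) induces pairwise genotype correlation with
    expectation ``within_block_r`` within blocks and 0 across blocks.
    Centimorgan positions jump ``cm_block_gap`` between blocks so the
    default 1 cM window covers exactly one block. The SNP table carries a
    ``block`` column for downstream diagnostics.
    """
    rng = _rng(cfg.seed, "panel")
    m, n = cfg.n_snps, cfg.n_samples
    block_of, within, block_r = _block_structure(
        rng, m, cfg.block_size, cfg.within_block_r
    )
    rsnp = block_r[block_of]
    factors = rng.standard_normal((n, block_of.max() + 1))
    noise = rng.standard_normal((n, m))
    latent = np.sqrt(rsnp) * factors[:, block_of] + np.sqrt(1 - rsnp) * noise
    maf = rng.uniform(*cfg.maf_range, size=m)
    if cfg.genotype_mode == "dosage":
        geno = 2 * maf + np.sqrt(2 * maf * (1 - maf)) * latent
    elif cfg.genotype_mode == "hard":
        latent2 = np.sqrt(rsnp) * rng.standard_normal((n, block_of.max() + 1))[
            :, block_of
        ] + np.sqrt(1 - rsnp) * rng.standard_normal((n, m))
        from scipy.stats import norm

        thr = norm.ppf(maf)
        geno = (latent < thr).astype(float) + (latent2 < thr).astype(float)
    else:
        raise ValueError(f"unknown genotype mode {cfg.genotype_mode!r}")
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": cfg.chrom,
            "pos": 1 + np.arange(m) * cfg.bp_spacing,
            "cm": block_of * cfg.cm_block_gap + within * 1e-3,
            "a1": "A",
            "a2": "G",
            "maf": np.minimum(np.nanmean(geno, axis=0) / 2, 1 - np.nanmean(geno, axis=0) / 2),
            "block": block_of,
        }
    )
    return SnpPanel(snps=snps, genotypes=geno)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(panel: SnpPanel, specs: list[AnnotationSpec], seed: int = 0) -> AnnotationStack:
    """Bernoulli binary / Beta probabilistic annotations plus an all-ones base."""
    annotations = []
    for i, spec in enumerate(specs):
        if not 0 < spec.coverage <= 1:
            raise ValueError(f"coverage for {spec.name!r} outside (0, 1]")
        rng = _rng(seed, "annotations", i)
        if spec.kind == "binary":
            values = (rng.random(panel.M) < spec.coverage).astype(float)
        elif spec.kind == "probabilistic":
            support = rng.random(panel.M) < spec.coverage
            values = np.where(support, rng.beta(2.0, 2.0, size=panel.M), 0.0)
        else:
            raise ValueError(f"unknown annotation kind {spec.kind!r}")
        annotations.append(Annotation(spec.name, values, spec.kind, spec.role))
    annotations.append(Annotation("base", np.ones(panel.M), "binary", "baseline"))
    return AnnotationStack(annotations)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def simulate_sumstats(
    panel: SnpPanel,
    stack: AnnotationStack,
    tau_true: np.ndarray,
    gwas_n: float,
    seed: int = 0,
    trait_index: int = 0,
    window: LdWindow | None = None,
    ldscore_table: LdScoreTable | None = None,
    ld_noise: bool = False,
    block_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> SumStats:
    """Marginal GWAS z-scores following the stratified heritability model.

    z_j = sqrt(1 + N * sum_c l(j,c) tau_c) * eps_j with standard-normal eps
    (independent by default), so E[chi2_j] matches the model exactly for the
    realized panel. ``ld_noise`` draws eps with within-block equicorrelation
    ``within-block r^2`` instead, for jackknife-calibration studies.
    Unadjusted LD scores are used so the expectation is exact.

    Replicate studies should pass one shared ``rng`` and draw successive
    traits from it, numpy's recommended pattern for Monte-Carlo loops;
    ``seed``/``trait_index`` instead derive a standalone named stream, which
    is convenient for one-off fixtures.
    """
    tau_true = np.asarray(tau_true, dtype=float)
    A = stack.matrix()
    var_beta = A @ tau_true
    if (var_beta < 0).any():
        warnings.warn("negative per-SNP effect variance truncated at 0")
    if ldscore_table is None:
        ldscore_table = ld_scores(panel, stack, window, adjusted=False)
    L = ldscore_table.scores()
    sigma2 = 1.0 + gwas_n * (L @ tau_true)
    if (sigma2 <= 0).any():
        raise ValueError("negative chi-square variance; tau_true too negative")
    if rng is None:
        rng = _rng(seed, "sumstats", trait_index)
    m = panel.M
    if ld_noise:
        bs = block_size or 20
        n_blocks = (m + bs - 1) // bs
        block_of = np.repeat(np.arange(n_blocks), bs)[:m]
        # equicorrelated noise within blocks at the squared genotype
        # correlation of the first block (an approximation to LD-correlated
        # marginal statistics, sufficient for jackknife calibration studies)
        r2 = 0.0
        if bs > 1 and m >= 2:
            x = panel.standardized()
            c = float(x[:, 0] @ x[:, 1]) / panel.n_samples
            r2 = min(max(c * c, 0.0), 0.99)
        f = rng.standard_normal(n_blocks)
        e = rng.standard_normal(m)
        eps = np.sqrt(r2) * f[block_of] + np.sqrt(1 - r2) * e
    else:
        eps = rng.standard_normal(m)
    z = np.sqrt(sigma2) * eps
    table = pd.DataFrame(
        {
            "snp_id": panel.snps["snp_id"],
            "a1": panel.snps["a1"],
            "a2": panel.snps["a2"],
            "n": float(gwas_n),
            "z": z,
        }
    )
    return SumStats(table)


def tau_for_tau_star(
    focal: Annotation, tau_base: float, M: int, target_tau_star: float
) -> float:
    """Focal tau giving the requested standardized effect size.

    Solves tau* = tau_f * sd_f / (h2_g / M) with
    h2_g = M * tau_base + S_f * tau_f, S_f the focal annotation's SNP sum.
    """
    sd_f = focal.sd
    s_f = float(focal.values.sum())
    denom = sd_f * M - target_tau_star * s_f
    if denom <= 0:
        raise ValueError("requested tau* unattainable for this annotation")
    return target_tau_star * M * tau_base / denom


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(cfg: SimConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Labeled cell x gene negative-binomial counts with planted markers.

    Each cell type's ``markers_per_type`` designated genes have their rate
    multiplied by ``marker_fold`` in that type. Returns the AnnData and a
    truth table of (gene, celltype) marker assignments.
    """
    if cfg.n_celltypes < 2:
        raise ValueError("need at least 2 cell types")
    if cfg.marker_fold <= 1:
        warnings.warn("marker_fold <= 1: markers are undetectable by design")
    rng = _rng(cfg.seed, "expression")
    cts = [f"ct{i + 1:02d}" for i in range(cfg.n_celltypes)]
    labels = np.repeat(cts, cfg.n_cells // cfg.n_celltypes)
    labels = np.concatenate([labels, rng.choice(cts, cfg.n_cells - len(labels))])
    genes = [f"gene{g + 1:04d}" for g in range(cfg.n_genes)]
    base_rate = rng.gamma(shape=2.0, scale=1.0, size=cfg.n_genes)
    truth_rows = []
    fold = np.ones((cfg.n_celltypes, cfg.n_genes))
    for i, ct in enumerate(cts):
        marker_idx = np.arange(i * cfg.markers_per_type, (i + 1) * cfg.markers_per_type)
        marker_idx = marker_idx[marker_idx < cfg.n_genes]
        fold[i, marker_idx] = cfg.marker_fold
        truth_rows += [{"gene": genes[g], "celltype": ct} for g in marker_idx]
    ct_index = np.array([cts.index(l) for l in labels])
    mu = base_rate[None, :] * fold[ct_index]
    r = cfg.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam)
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame({"cell_type": labels}, index=[f"cell{i}" for i in range(cfg.n_cells)]),
        var=pd.DataFrame({"gene": genes}, index=genes),
    )
    return adata, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def simulate_intervals(
    panel: SnpPanel, cfg: SimConfig, celltypes: list[str] | None = None, n_genes: int | None = None
) -> tuple[list[PeakSet], Intervals, pd.DataFrame]:
    """Per-cell-type peak sets, enhancer-gene links and gene bodies.

    Peaks cover a Bernoulli ``peak_coverage`` fraction of panel SNPs per cell
    type; gene bodies tile the panel; links connect one enhancer window per
    gene segment to its gene.
    """
    celltypes = celltypes or [f"ct{i + 1:02d}" for i in range(cfg.n_fixture_celltypes)]
    n_genes = n_genes or max(2, cfg.n_snps // 100)
    pos = panel.snps["pos"].to_numpy()
    chrom = panel.snps["chrom"].to_numpy()
    peak_sets = []
    for i, ct in enumerate(celltypes):
        rng = _rng(cfg.seed, "intervals", i)
        hit = rng.random(panel.M) < cfg.peak_coverage
        rows = [
            (chrom[j], max(pos[j] - 1 - cfg.peak_halfwidth, 0), pos[j] + cfg.peak_halfwidth)
            for j in np.flatnonzero(hit)
        ]
        iv = Intervals(pd.DataFrame(rows, columns=["chrom", "start", "end"])).merged()
        peak_sets.append(PeakSet(celltype=ct, intervals=iv))
    # gene bodies tile consecutive SNP segments
    rng = _rng(cfg.seed, "intervals", 10_000)
    seg = np.array_split(np.arange(panel.M), n_genes)
    gene_rows, link_rows = [], []
    for g, idx in enumerate(seg):
        if len(idx) == 0:
            continue
        name = f"gene{g + 1:04d}"
        c = chrom[idx[0]]
        body_lo = int(pos[idx[0]] - 1)
        body_hi = int(pos[idx[-1]])
        gene_rows.append((name, c, body_lo, body_hi))
        # one enhancer window per gene, anchored at a random SNP of the segment
        j = int(rng.choice(idx))
        e_lo = max(int(pos[j] - 1 - 5 * cfg.peak_halfwidth), 0)
        link_rows.append((c, e_lo, int(pos[j] + 5 * cfg.peak_halfwidth), name))
    genes = pd.DataFrame(gene_rows, columns=["gene", "chrom", "start", "end"])
    links = Intervals(pd.DataFrame(link_rows, columns=["chrom", "start", "end", "gene"]))
    return peak_sets, links, genes


# ---------------------------------------------------------------------------
# full fixture directory
# ---------------------------------------------------------------------------

def write_fixture(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Emit a complete analysis-ready fixture directory.

    Contents: text panel, per-cell-type peak BEDs, enhancer links, gene
    bodies, MatrixMarket expression triplet, per-trait sumstats, a baseline
    annot file (all-ones base annotation), a truth JSON naming the planted
    disease-critical cell type, and a ``design.yaml`` the CLI scan consumes.
    The first trait carries a focal effect of size ``target_tau_star`` on
    the first cell type; remaining traits are null beyond the baseline.
    """
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "sumstats").mkdir(exist_ok=True)
    (out / "expression").mkdir(exist_ok=True)
    panel = simulate_panel(cfg)
    write_panel_text(panel, out / "panel")
    peak_sets, links, genes = simulate_intervals(panel, cfg)
    for ps in peak_sets:
        write_intervals(ps.intervals, out / "peaks" / f"{ps.celltype}.bed")
    write_intervals(links, out / "links.bed")
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    adata, truth_markers = simulate_expression(cfg)
    scipy.io.mmwrite(str(out / "expression" / "matrix.mtx"), sp.coo_matrix(adata.X))
    adata.obs.reset_index(names="cell").to_csv(
        out / "expression" / "cells.tsv", sep="\t", index=False
    )
    adata.var.to_csv(out / "expression" / "genes.tsv", sep="\t", index=False)
    truth_markers.to_csv(out / "expression" / "marker_truth.tsv", sep="\t", index=False)
    # generating annotation stack: cell types + base + background
    ct_annots = [peaks_to_annotation(ps, panel) for ps in peak_sets]
    background = union_background(peak_sets, panel)
    base = Annotation("base", np.ones(panel.M), "binary", "baseline")
    stack = AnnotationStack(ct_annots + [base, background])
    write_annot(AnnotationStack([base]), panel, out / "baseline.annot")
    tau_base = cfg.h2_base / panel.M
    focal = ct_annots[0]
    tau_focal = tau_for_tau_star(focal, tau_base, panel.M, cfg.target_tau_star)
    ldt = ld_scores(panel, stack, LdWindow(), adjusted=False)
    traits = [f"trait_{i + 1:02d}" for i in range(cfg.n_traits)]
    for i, trait in enumerate(traits):
        tau = np.zeros(len(stack))
        tau[stack.names.index("base")] = tau_base
        if i == 0:
            tau[0] = tau_focal
        ss = simulate_sumstats(
            panel, stack, tau, cfg.gwas_n, seed=cfg.seed, trait_index=i, ldscore_table=ldt
        )
        write_sumstats(ss, out / "sumstats" / f"{trait}.sumstats")
    truth = {
        "planted_trait": traits[0],
        "planted_celltype": focal.name,
        "tau_base": tau_base,
        "tau_focal": tau_focal,
        "target_tau_star": cfg.target_tau_star,
        "celltypes": [ps.celltype for ps in peak_sets],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    design = {
        "panel": "panel",
        "baseline_annot": "baseline.annot",
        "window": {"mode": "cm", "size": 1.0},
        "q_threshold": 0.05,
        "datasets": {"sim_atac": {"kind": "atac", "peaks_dir": "peaks"}},
        "traits": {t: f"sumstats/{t}.sumstats" for t in traits},
    }
    (out / "design.yaml").write_text(yaml.safe_dump(design, sort_keys=False))
    return truth
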