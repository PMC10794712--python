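"""Trait x cell-type association scan.

For each dataset, every (trait, cell type) pair gets its own conditional
heritability fit: the focal cell-type annotation plus the shared baseline
annotations and the dataset's background annotation. Pairs with negative
standardized effect size are excluded from multiple testing; the remaining
one-sided p-values for positive tau* are Benjamini-Hochberg corrected within
the dataset (traits x cell types form one family), calling significance at
q < 0.05 with a Bonferroni flag reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .atac import annotation_correlation
from .io import Annotation, AnnotationStack, AssociationTable, SnpPanel, SumStats
from .ldscores import LdScoreTable, LdWindow, ld_scores
from .model import RegressionConfig, StratifiedHeritabilityModel, filter_regression_snps

logger = logging.getLogger("h2scan")

__all__ = [
    "StudyDesign",
    "reference_study_design",
    "enumerate_pairs",
    "prune_traits",
    "scan",
    "fdr",
    "concordance",
]


@dataclass
class StudyDesign:
    """Traits, per-dataset cell-type rosters and the trait correlation matrix.

    ``traits``: DataFrame with columns trait, h2_z and optionally a sumstats
    path. ``datasets``: dataset name -> ordered cell-type roster.
    ``genetic_correlation``: precomputed trait x trait correlation matrix.
    """

    traits: pd.DataFrame
    datasets: dict[str, list[str]]
    genetic_correlation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        g = self.genetic_correlation
        if g is not None:
            if not np.allclose(g.to_numpy(), g.to_numpy().T):
                raise ValueError("genetic correlation matrix must be symmetric")
            if not np.allclose(np.diag(g.to_numpy()), 1.0):
                raise ValueError("genetic correlation matrix must have unit diagonal")

    def pair_counts(self) -> dict[str, int]:
        """Planned (trait, cell type) pair count per dataset."""
        n_traits = len(self.traits)
        return {name: n_traits * len(roster) for name, roster in self.datasets.items()}

    @property
    def n_celltypes(self) -> int:
        return sum(len(r) for r in self.datasets.values())


def reference_study_design() -> StudyDesign:
    """The published brain compendium layout: 28 distinct brain traits scanned
    against four single-cell datasets (fetal scATAC 14 cell types, fetal
    scRNA 34, adult scATAC 18, adult scRNA 17; 83 cell types in all)."""
    traits = pd.DataFrame(
        {"trait": [f"brain_trait_{i + 1:02d}" for i in range(28)], "h2_z": np.nan}
    )
    datasets = {
        "fetal_atac": [f"fetal_atac_ct{i + 1:02d}" for i in range(14)],
        "fetal_rna": [f"fetal_rna_ct{i + 1:02d}" for i in range(34)],
        "adult_atac": [f"adult_atac_ct{i + 1:02d}" for i in range(18)],
        "adult_rna": [f"adult_rna_ct{i + 1:02d}" for i in range(17)],
    }
    return StudyDesign(traits=traits, datasets=datasets)


def enumerate_pairs(design: StudyDesign, dataset: str) -> list[tuple[str, str]]:
    """All (trait, cell type) pairs the scan will fit for one dataset."""
    roster = design.datasets[dataset]
    return [(t, ct) for t in design.traits["trait"] for ct in roster]


def prune_traits(design: StudyDesign, r_max: float = 0.9) -> list[str]:
    """Greedy pruning of genetically redundant traits.

    While any retained pair has |r| >= r_max, the most correlated pair is
    resolved by dropping its member with the lower SNP-heritability z-score
    (ties drop the lexicographically later trait id).
    """
    g = design.genetic_correlation
    if g is None:
        raise ValueError("design has no genetic correlation matrix")
    traits = list(design.traits["trait"])
    missing = [t for t in traits if t not in g.index or t not in g.columns]
    if missing:
        raise ValueError(f"genetic correlation matrix missing traits: {missing}")
    z = dict(zip(design.traits["trait"], design.traits["h2_z"]))
    retained = list(traits)
    while True:
        pairs = [
            (a, b)
            for i, a in enumerate(retained)
            for b in retained[i + 1 :]
            if abs(g.loc[a, b]) >= r_max
        ]
        if not pairs:
            return retained
        # resolve the strongest correlation first; deterministic tie-break
        pairs.sort(key=lambda p: (-abs(g.loc[p[0], p[1]]), p[0], p[1]))
        a, b = pairs[0]
        if z[a] < z[b] or (z[a] == z[b] and a > b):
            retained.remove(a)
        else:
            retained.remove(b)


def scan(
    panel: SnpPanel,
    celltype_annotations: list[Annotation],
    conditioning: list[Annotation],
    sumstats: dict[str, SumStats],
    dataset: str = "dataset",
    window: LdWindow | None = None,
    config: RegressionConfig | None = None,
    regression_snps: set[str] | None = None,
    ldscore_table: LdScoreTable | None = None,
) -> AssociationTable:
    """Fit every (trait, cell type) pair conditionally; returns pre-FDR rows.

    ``conditioning`` holds the baseline annotations plus the dataset
    background; each pair's model stacks the focal cell-type annotation on
    top of it. LD scores are computed once across all annotations (or passed
    in via ``ldscore_table``) and sliced per fit. A failed fit flags its row
    (NaN statistics) and the scan continues.
    """
    config = config or RegressionConfig()
    full_stack = AnnotationStack(list(celltype_annotations) + list(conditioning))
    if ldscore_table is None:
        ldscore_table = ld_scores(panel, full_stack, window, regression_snps)
    cond_names = [a.name for a in conditioning]
    rows = []
    for trait, ss in sumstats.items():
        try:
            ss_f, tbl_f, _ = filter_regression_snps(ss, ldscore_table, config)
        except ValueError as err:
            logger.warning("trait %s: %s", trait, err)
            ss_f = tbl_f = None
        for focal in celltype_annotations:
            row = {"trait": trait, "celltype": focal.name, "dataset": dataset}
            try:
                if tbl_f is None:
                    raise ValueError("no usable regression SNPs")
                names = [focal.name] + cond_names
                sub = LdScoreTable(
                    table=tbl_f.table[["snp_id", "chrom", "pos", *names]],
                    annotation_names=names,
                    window_spec=tbl_f.window_spec,
                )
                stack = AnnotationStack([focal] + list(conditioning))
                res = StratifiedHeritabilityModel(
                    ss_f, sub, stack, config=config, M=panel.M
                ).fit()
                row.update(
                    tau_star=float(res.tau_star[focal.name]),
                    se=float(res.tau_star_se[focal.name]),
                    p=float(res.p_pos_tau_star[focal.name]),
                    enrichment=float(res.enrichment[focal.name]),
                    failed=False,
                )
            except (ValueError, np.linalg.LinAlgError) as err:
                logger.warning("fit failed for (%s, %s): %s", trait, focal.name, err)
                row.update(tau_star=np.nan, se=np.nan, p=np.nan, enrichment=np.nan, failed=True)
            rows.append(row)
    return AssociationTable(pd.DataFrame(rows))


def fdr(
    table: AssociationTable,
    q_threshold: float = 0.05,
    bonferroni_pre_exclusion: bool = False,
) -> AssociationTable:
    """Per-dataset Benjamini-Hochberg FDR with negative-tau* exclusion.

    Rows with tau* < 0 (or failed fits) are excluded from the family and can
    never be significant. Significance is q < ``q_threshold``; a Bonferroni
    flag at 0.05 is reported with the family size counted after exclusion by
    default (``bonferroni_pre_exclusion`` switches to the pre-exclusion
    count).
    """
    t = table.table.copy()
    t["excluded_negative"] = (t["tau_star"] < 0) | t["p"].isna()
    t["q"] = np.nan
    t["significant"] = False
    t["bonferroni"] = False
    for _, idx in t.groupby("dataset").groups.items():
        sub = t.loc[idx]
        family = sub.index[~sub["excluded_negative"]]
        m_pre = len(sub)
        m = len(family)
        if m == 0:
            continue
        p = t.loc[family, "p"].to_numpy()
        _, q, _, _ = multipletests(p, method="fdr_bh")
        t.loc[family, "q"] = q
        t.loc[family, "significant"] = (q < q_threshold) & (
            t.loc[family, "tau_star"].to_numpy() > 0
        )
        denom = m_pre if bonferroni_pre_exclusion else m
        t.loc[family, "bonferroni"] = (p * denom < 0.05) & (
            t.loc[family, "tau_star"].to_numpy() > 0
        )
    return AssociationTable(t)


def concordance(
    table_a: AssociationTable,
    table_b: AssociationTable,
    annotations_a: dict[str, Annotation] | None = None,
    annotations_b: dict[str, Annotation] | None = None,
) -> dict:
    """Cross-platform agreement of two scans on matched (trait, cell type) rows.

    Returns the Pearson correlation of -log10 p across matched rows and,
    when per-cell-type annotations are supplied, the companion annotation-
    level correlations for matched cell-type names.
    """
    keys = ["trait", "celltype"]
    merged = table_a.table.merge(table_b.table, on=keys, suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["p_a", "p_b"])
    if len(merged) < 3:
        raise ValueError("need at least 3 matched rows for concordance")
    la = -np.log10(np.clip(merged["p_a"].to_numpy(), 1e-300, None))
    lb = -np.log10(np.clip(merged["p_b"].to_numpy(), 1e-300, None))
    r = float(np.corrcoef(la, lb)[0, 1])
    out = {"r_log10p": r, "n_matched": len(merged)}
    if annotations_a and annotations_b:
        shared = sorted(set(annotations_a) & set(annotations_b))
        out["annotation_r"] = {
            ct: annotation_correlation(annotations_a[ct], annotations_b[ct])
            for ct in shared
        }
    return out
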