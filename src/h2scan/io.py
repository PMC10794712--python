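"""Domain containers and on-disk formats.

The pipeline passes around a small set of typed containers: a reference SNP
panel with genotypes (:class:`SnpPanel`), per-SNP annotations in [0, 1]
(:class:`Annotation`, grouped into an :class:`AnnotationStack`), GWAS summary
statistics (:class:`SumStats`), stratified LD scores (:class:`LdScoreTable`)
and the trait x cell-type results table (:class:`AssociationTable`).

On-disk dialects handled here:

* PLINK ``.bed/.bim/.fam`` triplets, or a plain-text panel
  (``<prefix>.snps.tsv`` + ``<prefix>.geno.txt``) for tests and fixtures;
* LDSC-style ``.sumstats`` tables (SNP, A1, A2, N, Z);
* ldsc-style ``.annot`` tables (CHR, BP, SNP, CM, one column per annotation);
* BED peak files and BED+gene enhancer-link files;
* results TSVs.

Coordinates: BED intervals are 0-based half-open; panel positions and annot
files are 1-based. Conversion happens only inside overlap queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("h2scan")

__all__ = [
    "SnpPanel",
    "Annotation",
    "AnnotationStack",
    "SumStats",
    "LdScoreTable",
    "AssociationTable",
    "Intervals",
    "read_panel",
    "write_panel_text",
    "write_panel_plink",
    "read_sumstats",
    "write_sumstats",
    "read_intervals",
    "write_intervals",
    "read_annot",
    "write_annot",
    "read_results",
    "write_results",
    "align_sumstats",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SnpPanel:
    """Reference panel: SNP metadata plus a samples x SNPs genotype matrix.

    ``snps`` columns: snp_id, chrom, pos (1-based), cm, a1, a2, maf; rows are
    ordered by (chrom, pos) and positions are strictly increasing within a
    chromosome. ``genotypes`` holds allele-1 dosages (0..2, hard calls or
    continuous dosages); missing values are NaN and are mean-imputed by
    :meth:`standardized`.
    """

    snps: pd.DataFrame
    genotypes: np.ndarray
    _std: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        dup = self.snps["snp_id"][self.snps["snp_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate SNP id: {dup.iloc[0]!r}")
        if self.genotypes.shape[1] != len(self.snps):
            raise ValueError("genotype matrix width does not match SNP table")
        for _, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions not strictly increasing within chromosome")

    @property
    def M(self) -> int:
        """Number of retained panel SNPs."""
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    def dosage_filled(self) -> np.ndarray:
        """Genotypes with missing values mean-imputed per SNP."""
        g = np.asarray(self.genotypes, dtype=float)
        if not np.isnan(g).any():
            return g
        g = g.copy()
        mean = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = mean[idx[1]]
        return g

    def standardized(self) -> np.ndarray:
        """Per-SNP standardized (mean 0, variance 1) genotypes; cached."""
        if self._std is None:
            g = self.dosage_filled()
            mu = g.mean(axis=0)
            sd = g.std(axis=0)
            if np.any(sd == 0):
                j = int(np.argmax(sd == 0))
                raise ValueError(
                    f"monomorphic SNP {self.snps['snp_id'].iloc[j]!r}; "
                    "filter by MAF before use"
                )
            object.__setattr__(self, "_std", (g - mu) / sd)
        return self._std

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chrom, slice) pairs in panel order."""
        out: list[tuple[str, slice]] = []
        chroms = self.snps["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], slice(start, i)))
                start = i
        return out


@dataclass
class Annotation:
    """One per-SNP annotation: values in [0, 1] aligned to a panel."""

    name: str
    values: np.ndarray
    kind: str = "binary"  # binary | probabilistic
    role: str = "celltype"  # celltype | baseline | background

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("annotation values must be a vector")
        if np.any(~np.isfinite(self.values)):
            raise ValueError(f"annotation {self.name!r} has non-finite values")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError(f"annotation {self.name!r} values outside [0, 1]")
        if self.kind == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError(f"binary annotation {self.name!r} has non-0/1 values")

    @property
    def sd(self) -> float:
        """Standard deviation of annotation values across panel SNPs."""
        return float(np.std(self.values))


@dataclass
class AnnotationStack:
    """Ordered annotations sharing one panel; at most one focal cell type per fit."""

    annotations: list[Annotation]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(a.values) for a in self.annotations}
        if len(lengths) > 1:
            raise ValueError("annotations in a stack must share one panel length")
        names = [a.name for a in self.annotations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate annotation names in stack")

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.annotations]

    def matrix(self) -> np.ndarray:
        """Panel-SNPs x annotations value matrix."""
        return np.column_stack([a.values for a in self.annotations])

    def __len__(self) -> int:
        return len(self.annotations)

    def __getitem__(self, name: str) -> Annotation:
        for a in self.annotations:
            if a.name == name:
                return a
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "AnnotationStack":
        return AnnotationStack([self[n] for n in names])


@dataclass
class SumStats:
    """GWAS summary statistics: one row per SNP with z, chi2 = z**2 and N."""

    table: pd.DataFrame  # columns: snp_id, a1, a2, n, z, chi2

    def __post_init__(self) -> None:
        t = self.table
        if "chi2" not in t.columns:
            t = t.assign(chi2=t["z"] ** 2)
            self.table = t
        if len(t) and not np.allclose(t["chi2"], t["z"] ** 2):
            raise ValueError("chi2 column inconsistent with z**2")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_id(self) -> pd.Series:
        return self.table["snp_id"]

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy(dtype=float)

    @property
    def chi2(self) -> np.ndarray:
        return self.table["chi2"].to_numpy(dtype=float)

    @property
    def n(self) -> np.ndarray:
        return self.table["n"].to_numpy(dtype=float)


@dataclass
class LdScoreTable:
    """Stratified LD scores for the regression SNPs.

    ``table`` columns: snp_id, chrom, pos, then one score column per
    annotation (names in ``annotation_names``).
    """

    table: pd.DataFrame
    annotation_names: list[str]
    window_spec: str = ""

    def __post_init__(self) -> None:
        sc = self.scores()
        if not np.all(np.isfinite(sc)):
            raise ValueError("LD scores must be finite")

    def scores(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = list(names) if names is not None else self.annotation_names
        return self.table[names].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AssociationTable:
    """Trait x cell-type scan results.

    Columns: trait, celltype, dataset, tau_star, se, p, and after FDR also
    q, significant, bonferroni, excluded_negative.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class Intervals:
    """Genomic intervals (0-based half-open), optionally tagged with genes/scores.

    ``table`` columns: chrom, start, end [, gene, score]; sorted by
    (chrom, start, end).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and (t["end"].to_numpy() <= t["start"].to_numpy()).any():
            bad = int(np.argmax(t["end"].to_numpy() <= t["start"].to_numpy()))
            raise ValueError(f"interval end <= start at record {bad + 1}")
        self.table = t.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def merged(self) -> "Intervals":
        """Union of intervals per chromosome (gene/score columns dropped)."""
        rows = []
        for chrom, grp in self.table.groupby("chrom", sort=True):
            start = end = None
            for s, e in zip(grp["start"], grp["end"]):
                if start is None:
                    start, end = s, e
                elif s <= end:
                    end = max(end, e)
                else:
                    rows.append((chrom, start, end))
                    start, end = s, e
            if start is not None:
                rows.append((chrom, start, end))
        return Intervals(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def contains(self, chrom: np.ndarray, pos_1based: np.ndarray) -> np.ndarray:
        """Membership of 1-based point positions in the merged interval union."""
        merged = self.merged().table
        out = np.zeros(len(pos_1based), dtype=bool)
        pos0 = np.asarray(pos_1based) - 1
        chrom = np.asarray(chrom)
        for c, grp in merged.groupby("chrom", sort=False):
            mask = chrom == c
            if not mask.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            p = pos0[mask]
            idx = np.searchsorted(starts, p, side="right") - 1
            hit = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
            out[mask] = hit
        return out


# ---------------------------------------------------------------------------
# panel IO
# ---------------------------------------------------------------------------

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])


def _ext(prefix: Path, ext: str) -> Path:
    """PLINK-style prefix + extension (never replaces an existing suffix)."""
    return Path(str(prefix) + ext)
# 2-bit PLINK codes -> allele-1 dosage (01 = missing)
_PLINK_CODE = np.array([2.0, np.nan, 1.0, 0.0])


def _read_plink(prefix: Path) -> tuple[pd.DataFrame, np.ndarray]:
    bim = pd.read_csv(
        _ext(prefix, ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(_ext(prefix, ".fam"), sep=r"\s+", header=None)
    n = len(fam)
    raw = np.fromfile(_ext(prefix, ".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    m = len(bim)
    if len(body) != bytes_per_snp * m:
        raise ValueError(f"{prefix}.bed size inconsistent with .bim/.fam")
    codes = body.reshape(m, bytes_per_snp)[:, :, None] >> (2 * np.arange(4))
    codes = (codes & 0b11).reshape(m, -1)[:, :n]
    geno = _PLINK_CODE[codes].T  # samples x SNPs
    return bim, geno


def write_panel_plink(panel: SnpPanel, prefix: str | Path) -> None:
    """Write a panel as a PLINK triplet (genotypes rounded to hard calls)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    s = panel.snps
    pd.DataFrame(
        {
            "chrom": s["chrom"],
            "snp_id": s["snp_id"],
            "cm": s["cm"],
            "pos": s["pos"],
            "a1": s["a1"],
            "a2": s["a2"],
        }
    ).to_csv(_ext(prefix, ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(panel.n_samples)],
            "iid": [f"I{i}" for i in range(panel.n_samples)],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(_ext(prefix, ".fam"), sep="\t", header=False, index=False)
    g = np.clip(np.round(panel.dosage_filled()), 0, 2)
    code = np.where(g == 2, 0, np.where(g == 1, 2, 3)).astype(np.uint8)  # dosage->2bit
    n, m = code.shape
    pad = (-n) % 4
    if pad:
        code = np.vstack([code, np.full((pad, m), 3, dtype=np.uint8)])
        code[n:, :] = 0  # pad slots read as hom-a1 but are never consumed
    quads = code.T.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        packed.tofile(fh)


def write_panel_text(panel: SnpPanel, prefix: str | Path) -> None:
    """Write a panel as ``<prefix>.snps.tsv`` + ``<prefix>.geno.txt``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    panel.snps.drop(columns=["maf"], errors="ignore").to_csv(
        Path(str(prefix) + ".snps.tsv"), sep="\t", index=False
    )
    np.savetxt(Path(str(prefix) + ".geno.txt"), panel.genotypes, fmt="%.4f")


def _read_panel_text(prefix: Path) -> tuple[pd.DataFrame, np.ndarray]:
    snps = pd.read_csv(
        Path(str(prefix) + ".snps.tsv"), sep="\t", dtype={"chrom": str, "snp_id": str}
    )
    geno = np.loadtxt(Path(str(prefix) + ".geno.txt"), ndmin=2)
    return snps, geno


def read_panel(path: str | Path, maf_min: float = 0.005) -> SnpPanel:
    """Read a reference panel and apply the MAF filter.

    ``path`` is a PLINK prefix (``.bed/.bim/.fam``) or a plain-text prefix
    (``.snps.tsv`` + ``.geno.txt``). SNPs with MAF below ``maf_min`` are
    removed; the panel is ordered deterministically by (chrom, pos).
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    prefix = Path(path)
    if _ext(prefix, ".bed").exists():
        snps, geno = _read_plink(prefix)
    elif Path(str(prefix) + ".snps.tsv").exists():
        snps, geno = _read_panel_text(prefix)
    else:
        raise FileNotFoundError(f"no PLINK triplet or text panel at {path!r}")
    if "cm" not in snps.columns:
        logger.warning("panel %s lacks a cM column; imputing cM = 0", path)
        snps = snps.assign(cm=0.0)
    snps = snps.reset_index(drop=True)
    freq = np.nanmean(geno, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    snps = snps.assign(maf=maf)
    keep = maf >= maf_min
    snps = snps.loc[keep].reset_index(drop=True)
    geno = geno[:, keep]
    order = np.lexsort((snps["pos"].to_numpy(), snps["chrom"].to_numpy()))
    snps = snps.iloc[order].reset_index(drop=True)
    geno = geno[:, order]
    return SnpPanel(snps=snps, genotypes=geno)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_sumstats(path: str | Path) -> SumStats:
    """Read an LDSC-dialect sumstats table (SNP, A1, A2, N, Z; any case)."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("snp", "z"):
        if required not in cols:
            raise ValueError(f"sumstats {path!r} missing required column {required.upper()}")
    out = pd.DataFrame({"snp_id": df[cols["snp"]]})
    out["a1"] = df[cols["a1"]] if "a1" in cols else ""
    out["a2"] = df[cols["a2"]] if "a2" in cols else ""
    for name, col in (("n", "n"), ("z", "z")):
        if col not in cols:
            raise ValueError(f"sumstats {path!r} missing required column {col.upper()}")
        vals = pd.to_numeric(df[cols[col]], errors="coerce")
        bad = vals.isna() & df[cols[col]].notna()
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2  # 1-based incl. header
            raise ValueError(f"non-numeric {col.upper()} in {path!r} at line {line}")
        out[name] = vals.astype(float)
    out["chi2"] = out["z"] ** 2
    return SumStats(out)


def write_sumstats(ss: SumStats, path: str | Path) -> None:
    t = ss.table
    pd.DataFrame(
        {"SNP": t["snp_id"], "A1": t["a1"], "A2": t["a2"], "N": t["n"], "Z": t["z"]}
    ).to_csv(path, sep="\t", index=False)


def align_sumstats(ss: SumStats, panel_snps: pd.DataFrame) -> SumStats:
    """Restrict sumstats to panel SNPs, dropping allele-mismatched records.

    Matching is on SNP id; when both sides carry alleles, a record whose
    unordered {A1, A2} differs from the panel's is logged and dropped (only
    chi-square enters the regression, so the sign of Z never matters).
    """
    t = ss.table.merge(
        panel_snps[["snp_id", "a1", "a2"]].rename(columns={"a1": "p_a1", "a2": "p_a2"}),
        on="snp_id",
        how="inner",
    )
    has = (t["a1"].astype(str) != "") & (t["a2"].astype(str) != "")
    ok = np.ones(len(t), dtype=bool)
    if has.any():
        sa = t["a1"].astype(str).str.upper()
        sb = t["a2"].astype(str).str.upper()
        pa = t["p_a1"].astype(str).str.upper()
        pb = t["p_a2"].astype(str).str.upper()
        match = ((sa == pa) & (sb == pb)) | ((sa == pb) & (sb == pa))
        ok = ~has.to_numpy() | match.to_numpy()
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("dropping %d sumstats SNPs with allele mismatch", n_bad)
    t = t.loc[ok].drop(columns=["p_a1", "p_a2"]).reset_index(drop=True)
    return SumStats(t)


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, dialect: str = "bed_peaks") -> Intervals:
    """Read a BED file (``bed_peaks``) or BED+gene link file (``enhancer_links``).

    BED is 0-based half-open. The link dialect expects a 4th ``gene`` column
    and an optional 5th ``score`` column; gene names pass through verbatim.
    """
    if dialect not in ("bed_peaks", "enhancer_links"):
        raise ValueError(f"unknown interval dialect {dialect!r}")
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype={0: str})
    names = ["chrom", "start", "end"]
    if dialect == "enhancer_links":
        names += ["gene", "score"]
    if df.shape[1] < (4 if dialect == "enhancer_links" else 3):
        raise ValueError(f"{path!r}: too few columns for dialect {dialect!r}")
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    if "gene" in df.columns:
        df["gene"] = df["gene"].astype(str)
    bad = df["end"].to_numpy() <= df["start"].to_numpy()
    if bad.any():
        raise ValueError(f"interval end <= start in {path!r} at line {int(np.argmax(bad)) + 1}")
    return Intervals(df)


def write_intervals(iv: Intervals, path: str | Path) -> None:
    iv.table.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# annot tables
# ---------------------------------------------------------------------------

def write_annot(stack: AnnotationStack, panel: SnpPanel, path: str | Path) -> None:
    """Write an ldsc-dialect annot TSV: CHR, BP, SNP, CM, one column per annotation."""
    if len(stack.annotations) and len(stack.annotations[0].values) != panel.M:
        raise ValueError("annotation length does not match panel M")
    out = pd.DataFrame(
        {
            "CHR": panel.snps["chrom"],
            "BP": panel.snps["pos"],
            "SNP": panel.snps["snp_id"],
            "CM": panel.snps["cm"],
        }
    )
    for a in stack.annotations:
        out[a.name] = np.round(a.values, 6)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_annot(path: str | Path) -> tuple[pd.DataFrame, AnnotationStack]:
    """Read an annot TSV; returns the SNP coordinate frame and the stack.

    Kind is inferred (binary iff all values are 0/1); roles default to
    ``celltype`` and can be reassigned by the caller.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SNP": str})
    meta_cols = ["CHR", "BP", "SNP", "CM"]
    ann_cols = [c for c in df.columns if c not in meta_cols]
    annotations = []
    for c in ann_cols:
        vals = df[c].to_numpy(dtype=float)
        kind = "binary" if np.isin(vals, (0.0, 1.0)).all() else "probabilistic"
        annotations.append(Annotation(name=c, values=vals, kind=kind))
    return df[meta_cols], AnnotationStack(annotations)


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

def write_results(table: AssociationTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> AssociationTable:
    return AssociationTable(pd.read_csv(path, sep="\t"))


def validate(path: str | Path) -> dict:
    """Best-effort dialect sniffing for `h2scan io validate`."""
    p = Path(path)
    if (_ext(p, ".bed").exists() and _ext(p, ".bim").exists()) or Path(
        str(p) + ".snps.tsv"
    ).exists():
        panel = read_panel(p, maf_min=0.0)
        return {"dialect": "panel", "records": panel.M, "samples": panel.n_samples}
    head = pd.read_csv(p, sep=r"\s+", nrows=1)
    cols = {c.lower() for c in head.columns}
    if {"snp", "z"} <= cols:
        return {"dialect": "sumstats", "records": len(read_sumstats(p))}
    if {"chr", "bp", "snp", "cm"} <= cols:
        meta, stack = read_annot(p)
        return {"dialect": "annot", "records": len(meta), "annotations": len(stack)}
    try:
        iv = read_intervals(p, "enhancer_links")
        return {"dialect": "enhancer_links", "records": len(iv)}
    except Exception:
        iv = read_intervals(p, "bed_peaks")
        return {"dialect": "bed_peaks", "records": len(iv)}
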