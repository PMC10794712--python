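"""Stratified heritability regression (Model/Results).

The model assumes each SNP's standardized effect-size variance decomposes
linearly over annotations, Var(beta_j) = sum_c a_cj * tau_c, which implies
for the GWAS chi-square statistics

    E[chi2_j] = N * sum_c l(j, c) * tau_c + 1,

where l(j, c) are the stratified LD scores and N the GWAS sample size. The
coefficients tau_c are estimated by (weighted) least squares of chi2 on
N * l(j, c); a delete-a-block jackknife over contiguous SNP blocks provides
the coefficient covariance. Derived quantities:

* total SNP heritability     h2_g = sum_j sum_c a_cj * tau_c,
* standardized effect size   tau*_c = tau_c * sd(a_c) / (h2_g / M),
* enrichment                 (h2(C) / h2_g) / (sum_j a_jC / M),

with one-sided significance for positive tau* from tau*/se ~ N(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationStack, LdScoreTable, SumStats

__all__ = [
    "RegressionConfig",
    "filter_regression_snps",
    "StratifiedHeritabilityModel",
    "StratifiedHeritabilityResults",
    "tau_star",
    "p_positive_tau_star",
]


@dataclass
class RegressionConfig:
    """Tuning of the chi-square regression.

    chi2_max (default 80) and the MHC interval (chr6:25-34 Mb, 1-based) are
    the standard regression-SNP exclusions. The intercept is free by default;
    ``fixed_one`` constrains it to the model's literal +1. Weighting
    ``two_part`` combines inverse heteroskedasticity weights from a
    provisional fit with inverse LD-overcounting weights (one iteration);
    ``ols`` is unweighted and is what exact oracles use.
    """

    n_jackknife_blocks: int = 200
    intercept_mode: str = "free"  # free | fixed_one
    chi2_max: float = 80.0
    mhc_chrom: str = "6"
    mhc_start: int = 25_000_000
    mhc_end: int = 34_000_000
    weighting: str = "two_part"  # two_part | ols

    def __post_init__(self) -> None:
        if self.intercept_mode not in ("free", "fixed_one"):
            raise ValueError(f"unknown intercept mode {self.intercept_mode!r}")
        if self.weighting not in ("two_part", "ols"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.n_jackknife_blocks < 2:
            raise ValueError("need at least 2 jackknife blocks")


def filter_regression_snps(
    ss: SumStats, table: LdScoreTable, cfg: RegressionConfig | None = None
) -> tuple[SumStats, LdScoreTable, dict]:
    """Intersect sumstats with LD-score SNPs and apply chi2/MHC exclusions.

    Returns the filtered pair plus a report of counts removed per rule.
    """
    cfg = cfg or RegressionConfig()
    t = table.table.merge(
        ss.table, left_on="snp_id", right_on="snp_id", how="inner", suffixes=("", "_ss")
    )
    if len(t) == 0:
        raise ValueError("no overlap between sumstats and LD-score SNPs")
    n_common = len(t)
    chrom = t["chrom"].astype(str).str.removeprefix("chr")
    mhc_chrom = str(cfg.mhc_chrom).removeprefix("chr")
    mhc = (chrom == mhc_chrom) & (t["pos"] >= cfg.mhc_start) & (t["pos"] <= cfg.mhc_end)
    high = t["chi2"] > cfg.chi2_max
    keep = ~(mhc | high)
    report = {
        "common": n_common,
        "removed_chi2": int(high.sum()),
        "removed_mhc": int((mhc & ~high).sum()),
        "retained": int(keep.sum()),
    }
    t = t.loc[keep].reset_index(drop=True)
    ss_cols = ["snp_id", "a1", "a2", "n", "z", "chi2"]
    ss_f = SumStats(t[[c for c in ss_cols if c in t.columns]].copy())
    tbl_f = LdScoreTable(
        table=t[["snp_id", "chrom", "pos", *table.annotation_names]].copy(),
        annotation_names=table.annotation_names,
        window_spec=table.window_spec,
    )
    return ss_f, tbl_f, report


def tau_star(tau: float, sd_a: float, h2g: float, M: int) -> float:
    """Standardized effect size: tau * sd(a) / (h2_g / M)."""
    if h2g <= 0:
        raise ValueError("tau* undefined for non-positive h2_g")
    return tau * sd_a / (h2g / M)


def p_positive_tau_star(ts: float, se: float) -> float:
    """One-sided p for positive tau*: 1 - Phi(tau*/se)."""
    if not se > 0:
        raise ValueError("standard error must be positive")
    return float(stats.norm.sf(ts / se))


def _blocks(n: int, n_blocks: int) -> list[slice]:
    """Contiguous equal-size blocks; the remainder is spread over leading blocks."""
    sizes = np.full(n_blocks, n // n_blocks)
    sizes[: n % n_blocks] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [slice(int(edges[i]), int(edges[i + 1])) for i in range(n_blocks)]


class StratifiedHeritabilityModel:
    """Chi-square regression of GWAS statistics on stratified LD scores.

    Parameters
    ----------
    sumstats, ldscores
        Aligned regression-SNP inputs (pass through
        :func:`filter_regression_snps` first, or set ``prefiltered=False``
        to have the model do it).
    stack
        Full-panel annotation stack; supplies annotation values for h2_g,
        tau* and enrichment. Column order must match ``ldscores``.
    M
        Number of panel SNPs used for h2_g (defaults to the stack length).
    """

    def __init__(
        self,
        sumstats: SumStats,
        ldscores: LdScoreTable,
        stack: AnnotationStack,
        config: RegressionConfig | None = None,
        M: int | None = None,
        prefiltered: bool = True,
    ) -> None:
        self.config = config or RegressionConfig()
        if not prefiltered:
            sumstats, ldscores, self.filter_report = filter_regression_snps(
                sumstats, ldscores, self.config
            )
        else:
            self.filter_report = None
        if list(ldscores.annotation_names) != list(stack.names):
            raise ValueError("LD-score columns do not match annotation stack")
        if not (ldscores.table["snp_id"].to_numpy() == sumstats.snp_id.to_numpy()).all():
            # align by id, preserving LD-score row order
            merged = ldscores.table[["snp_id"]].merge(sumstats.table, on="snp_id")
            if len(merged) != len(ldscores.table):
                raise ValueError("sumstats and LD scores disagree on SNP ids")
            sumstats = SumStats(merged)
        self.sumstats = sumstats
        self.ldscores = ldscores
        self.stack = stack
        self.M = M if M is not None else len(stack.annotations[0].values)
        n_ann = len(stack)
        if len(sumstats) < n_ann + 1:
            raise ValueError("need more regression SNPs than annotations")

    # -- design ---------------------------------------------------------

    def _design(self) -> tuple[np.ndarray, np.ndarray]:
        L = self.ldscores.scores()
        N = self.sumstats.n[:, None]
        X = N * L
        y = self.sumstats.chi2.copy()
        if self.config.intercept_mode == "free":
            X = np.column_stack([X, np.ones(len(y))])
        else:
            y = y - 1.0
        return X, y

    def _check_rank(self, X: np.ndarray) -> None:
        names = list(self.stack.names)
        if self.config.intercept_mode == "free":
            names.append("intercept")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            collinear = []
            for j in range(X.shape[1]):
                others = np.delete(X, j, axis=1)
                resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
                if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(X[:, j]), 1.0):
                    collinear.append(names[j])
            raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    def _weights(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.config.weighting == "ols":
            return np.ones(len(y))
        # one-iteration two-part weights: inverse heteroskedasticity from a
        # provisional OLS fit x inverse LD overcounting
        beta0 = np.linalg.lstsq(X, y, rcond=None)[0]
        pred = X @ beta0
        if self.config.intercept_mode == "fixed_one":
            pred = pred + 1.0
        pred = np.clip(pred, 1.0, None)
        L = self.ldscores.scores()
        base = None
        for i, a in enumerate(self.stack.annotations):
            if np.all(a.values == 1.0):
                base = L[:, i]
                break
        ld_w = np.clip(base if base is not None else L.max(axis=1), 1.0, None)
        return 1.0 / (2.0 * pred**2 * ld_w)

    # -- fitting --------------------------------------------------------

    def fit(self) -> "StratifiedHeritabilityResults":
        X, y = self._design()
        self._check_rank(X)
        w = self._weights(X, y)
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        yw = y * sw
        n_blocks = min(self.config.n_jackknife_blocks, len(y))
        blocks = _blocks(len(y), n_blocks)
        XtX_b = np.stack([Xw[b].T @ Xw[b] for b in blocks])
        Xty_b = np.stack([Xw[b].T @ yw[b] for b in blocks])
        XtX = XtX_b.sum(axis=0)
        Xty = Xty_b.sum(axis=0)
        theta = np.linalg.solve(XtX, Xty)
        theta_del = np.linalg.solve(XtX[None] - XtX_b, (Xty[None] - Xty_b)[..., None])[
            ..., 0
        ]
        B = n_blocks
        dev = theta_del - theta_del.mean(axis=0)
        cov = (B - 1) / B * (dev.T @ dev)
        return StratifiedHeritabilityResults(
            model=self, theta=theta, theta_del=theta_del, theta_cov=cov
        )


@dataclass
class StratifiedHeritabilityResults:
    """Fitted coefficients, jackknife uncertainty and derived h2 metrics."""

    model: StratifiedHeritabilityModel
    theta: np.ndarray  # tau_c (+ intercept last, in free mode)
    theta_del: np.ndarray  # delete-a-block estimates, blocks x params
    theta_cov: np.ndarray

    # -- coefficients ---------------------------------------------------

    @property
    def names(self) -> list[str]:
        return list(self.model.stack.names)

    @property
    def n_annotations(self) -> int:
        return len(self.model.stack)

    @property
    def tau(self) -> pd.Series:
        return pd.Series(self.theta[: self.n_annotations], index=self.names, name="tau")

    @property
    def tau_cov(self) -> np.ndarray:
        return self.theta_cov[: self.n_annotations, : self.n_annotations]

    @property
    def tau_se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.tau_cov)), index=self.names, name="tau_se"
        )

    @property
    def intercept(self) -> float:
        if self.model.config.intercept_mode == "free":
            return float(self.theta[-1])
        return 1.0

    @property
    def intercept_se(self) -> float:
        if self.model.config.intercept_mode == "free":
            return float(np.sqrt(self.theta_cov[-1, -1]))
        return 0.0

    @property
    def nobs(self) -> int:
        return len(self.model.sumstats)

    # -- derived heritability metrics ------------------------------------

    def _colsums(self) -> np.ndarray:
        return self.model.stack.matrix().sum(axis=0)

    @property
    def h2g(self) -> float:
        """Total SNP heritability: sum over panel SNPs of sum_c a_cj tau_c."""
        return float(self._colsums() @ self.tau.to_numpy())

    @property
    def h2g_se(self) -> float:
        s = self._colsums()
        dels = self.theta_del[:, : self.n_annotations] @ s
        B = len(dels)
        return float(np.sqrt((B - 1) / B * ((dels - dels.mean()) ** 2).sum()))

    @property
    def prop_snp(self) -> pd.Series:
        """Annotation share of SNPs: sum_j a_jC / M (mean value if probabilistic)."""
        A = self.model.stack.matrix()
        return pd.Series(A.sum(axis=0) / self.model.M, index=self.names, name="prop_snp")

    def _h2_per_annotation(self, tau_vec: np.ndarray) -> np.ndarray:
        """h2(C) = sum_j a_jC * (sum_c a_cj tau_c) for each annotation C."""
        A = self.model.stack.matrix()
        per_snp = A @ tau_vec
        return A.T @ per_snp

    @property
    def prop_h2(self) -> pd.Series:
        h2g = self.h2g
        if h2g <= 0:
            raise ValueError("proportion of heritability undefined: h2_g <= 0")
        return pd.Series(
            self._h2_per_annotation(self.tau.to_numpy()) / h2g,
            index=self.names,
            name="prop_h2",
        )

    @property
    def enrichment(self) -> pd.Series:
        """Share of heritability divided by share of SNPs, per annotation."""
        ps = self.prop_snp
        if (ps <= 0).any():
            bad = ps.index[ps <= 0][0]
            raise ValueError(f"annotation {bad!r} is empty; enrichment undefined")
        return pd.Series(
            self.prop_h2.to_numpy() / ps.to_numpy(), index=self.names, name="enrichment"
        )

    @property
    def enrichment_se(self) -> pd.Series:
        ps = self.prop_snp.to_numpy()
        s = self._colsums()
        taus = self.theta_del[:, : self.n_annotations]
        h2g_del = taus @ s
        with np.errstate(divide="ignore", invalid="ignore"):
            enr_del = np.stack(
                [self._h2_per_annotation(t) / h for t, h in zip(taus, h2g_del)]
            ) / ps
        B = len(enr_del)
        dev = enr_del - enr_del.mean(axis=0)
        se = np.sqrt((B - 1) / B * (dev**2).sum(axis=0))
        return pd.Series(se, index=self.names, name="enrichment_se")

    @property
    def annotation_sd(self) -> pd.Series:
        return pd.Series(
            [a.sd for a in self.model.stack.annotations], index=self.names, name="sd"
        )

    @property
    def tau_star(self) -> pd.Series:
        """Standardized effect sizes tau* = tau sd(a) / (h2_g / M)."""
        h2g = self.h2g
        if h2g <= 0:
            raise ValueError("tau* undefined: estimated h2_g <= 0")
        scale = self.annotation_sd.to_numpy() / (h2g / self.model.M)
        return pd.Series(
            self.tau.to_numpy() * scale, index=self.names, name="tau_star"
        )

    @property
    def tau_star_se(self) -> pd.Series:
        """Jackknife SE of tau propagated by the tau* scale factor."""
        h2g = self.h2g
        if h2g <= 0:
            raise ValueError("tau* undefined: estimated h2_g <= 0")
        scale = self.annotation_sd.to_numpy() / (h2g / self.model.M)
        return pd.Series(
            self.tau_se.to_numpy() * np.abs(scale), index=self.names, name="tau_star_se"
        )

    @property
    def p_pos_tau_star(self) -> pd.Series:
        ts = self.tau_star.to_numpy()
        se = self.tau_star_se.to_numpy()
        p = np.array(
            [p_positive_tau_star(t, s) if s > 0 else np.nan for t, s in zip(ts, se)]
        )
        return pd.Series(p, index=self.names, name="p_pos_tau_star")

    # -- presentation ----------------------------------------------------

    def frame(self) -> pd.DataFrame:
        """Per-annotation results table."""
        return pd.DataFrame(
            {
                "tau": self.tau,
                "tau_se": self.tau_se,
                "tau_star": self.tau_star,
                "tau_star_se": self.tau_star_se,
                "p_pos": self.p_pos_tau_star,
                "enrichment": self.enrichment,
                "enrichment_se": self.enrichment_se,
                "prop_h2": self.prop_h2,
                "prop_snp": self.prop_snp,
            }
        )

    def summary(self) -> str:
        cfg = self.model.config
        head = (
            "      Stratified heritability regression\n"
            "==============================================\n"
            f"regression SNPs: {self.nobs:>10d}   panel M: {self.model.M}\n"
            f"jackknife blocks: {min(cfg.n_jackknife_blocks, self.nobs):>9d}   "
            f"weighting: {cfg.weighting}\n"
            f"intercept ({cfg.intercept_mode}): "
            f"{self.intercept:.4f} ({self.intercept_se:.4f})\n"
            f"h2_g: {self.h2g:.4f} ({self.h2g_se:.4f})\n"
            "----------------------------------------------\n"
        )
        with pd.option_context("display.width", 120, "display.float_format", "{:.4g}".format):
            body = self.frame().to_string()
        return head + body + "\n==============================================\n"
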