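import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import h2scan as h
from h2scan.model import p_positive_tau_star, tau_star

from conftest import panel_from_arrays


def make_sumstats(panel, z, n=50_000.0):
    return h.SumStats(
        pd.DataFrame(
            {
                "snp_id": panel.snps["snp_id"],
                "a1": "A",
                "a2": "G",
                "n": n,
                "z": np.asarray(z, dtype=float),
            }
        )
    )


# ---------------------------------------------------------------------------
# regression-SNP filters
# ---------------------------------------------------------------------------

def test_filter_removes_high_chi2_and_mhc(medium_sim):
    _, panel, stack, lt_un, _ = medium_sim
    z = np.ones(panel.M)
    z[0] = 9.5  # chi2 = 90.25 > 80
    ss = make_sumstats(panel, z)
    # relocate one regression SNP into the MHC
    tbl = lt_un.table.copy()
    tbl.loc[1, ["chrom", "pos"]] = ["6", 30_000_000]
    lt = h.LdScoreTable(tbl, lt_un.annotation_names)
    ss_f, lt_f, report = h.filter_regression_snps(ss, lt)
    assert report["removed_chi2"] == 1 and report["removed_mhc"] == 1
    assert report["retained"] == panel.M - 2 == len(ss_f) == len(lt_f)


def test_filter_noop_on_clean_input(medium_sim):
    _, panel, stack, lt_un, _ = medium_sim
    ss = make_sumstats(panel, np.ones(panel.M))
    ss_f, _, report = h.filter_regression_snps(ss, lt_un)
    assert report["retained"] == panel.M and report["removed_chi2"] == 0


def test_filter_empty_intersection_errors(medium_sim):
    _, panel, _, lt_un, _ = medium_sim
    ss = h.SumStats(
        pd.DataFrame({"snp_id": ["nope"], "a1": "A", "a2": "G", "n": 1.0, "z": [1.0]})
    )
    with pytest.raises(ValueError, match="overlap"):
        h.filter_regression_snps(ss, lt_un)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_null_chi2_gives_zero_tau(medium_sim):
    _, panel, stack, lt_un, _ = medium_sim
    ss = make_sumstats(panel, np.ones(panel.M))
    res = h.StratifiedHeritabilityModel(
        ss, lt_un, stack, config=h.RegressionConfig(weighting="ols")
    ).fit()
    assert np.allclose(res.tau.to_numpy(), 0.0, atol=1e-14)
    assert res.intercept == pytest.approx(1.0)


def test_noiseless_exact_recovery(medium_sim):
    _, panel, stack, lt_un, _ = medium_sim
    tau_true = np.array([3e-5, 1e-5])
    chi2 = 1.0 + 50_000 * lt_un.scores() @ tau_true
    res = h.StratifiedHeritabilityModel(
        make_sumstats(panel, np.sqrt(chi2)),
        lt_un,
        stack,
        config=h.RegressionConfig(weighting="ols"),
    ).fit()
    assert np.max(np.abs(res.tau.to_numpy() / tau_true - 1)) < 1e-10
    assert res.intercept == pytest.approx(1.0, abs=1e-10)


def test_fixed_one_intercept_mode(medium_sim):
    _, panel, stack, lt_un, _ = medium_sim
    tau_true = np.array([3e-5, 1e-5])
    chi2 = 1.0 + 50_000 * lt_un.scores() @ tau_true
    res = h.StratifiedHeritabilityModel(
        make_sumstats(panel, np.sqrt(chi2)),
        lt_un,
        stack,
        config=h.RegressionConfig(weighting="ols", intercept_mode="fixed_one"),
    ).fit()
    assert np.max(np.abs(res.tau.to_numpy() / tau_true - 1)) < 1e-10
    assert res.intercept == 1.0


def test_ols_fit_equals_normal_equations(medium_sim):
    """Independent closed-form oracle for the point estimates."""
    _, panel, stack, lt_un, _ = medium_sim
    rng = np.random.default_rng(8)
    ss = make_sumstats(panel, rng.normal(1, 0.5, panel.M))
    res = h.StratifiedHeritabilityModel(
        ss, lt_un, stack, config=h.RegressionConfig(weighting="ols")
    ).fit()
    X = np.column_stack([50_000 * lt_un.scores(), np.ones(panel.M)])
    y = ss.chi2
    theta = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(res.theta, theta, rtol=1e-9)


def test_rank_deficient_design_names_columns(medium_sim):
    _, panel, stack, lt_un, _ = medium_sim
    dup = h.Annotation("focal_copy", stack["focal"].values, "binary")
    stack2 = h.AnnotationStack(list(stack.annotations) + [dup])
    tbl = lt_un.table.copy()
    tbl["focal_copy"] = tbl["focal"]
    lt2 = h.LdScoreTable(tbl, lt_un.annotation_names + ["focal_copy"])
    ss = make_sumstats(panel, np.ones(panel.M))
    with pytest.raises(ValueError, match="focal"):
        h.StratifiedHeritabilityModel(ss, lt2, stack2).fit()


def test_jackknife_se_matches_analytic_ols_on_homoskedastic_data():
    """With iid noise the block jackknife agrees with the textbook OLS SE."""
    cfg = h.SimConfig(seed=21, n_snps=5000, n_samples=300)
    panel = h.simulate_panel(cfg)
    stack = h.simulate_annotations(panel, [h.AnnotationSpec("focal", 0.2)], seed=21)
    lt = h.ld_scores(panel, stack, h.LdWindow(), adjusted=False)
    tau_true = np.array([2e-5, 2e-5])
    rng = np.random.default_rng(22)
    mean = 1.0 + 50_000 * lt.scores() @ tau_true
    y = mean + rng.normal(0, 0.4, panel.M)  # homoskedastic, stays positive
    assert (y > 0).all()
    res = h.StratifiedHeritabilityModel(
        make_sumstats(panel, np.sqrt(y)), lt, stack, config=h.RegressionConfig(weighting="ols")
    ).fit()
    X = sm.add_constant(50_000 * lt.scores(), prepend=False)
    analytic = sm.OLS(y, X).fit().bse
    ratio = res.tau_se.to_numpy() / analytic[:2]
    assert ((ratio > 0.8) & (ratio < 1.25)).all()


# ---------------------------------------------------------------------------
# tau*, enrichment, p-values
# ---------------------------------------------------------------------------

def test_tau_star_direct_evaluation():
    assert tau_star(0.0, 0.05, 0.5, 1000) == 0.0
    assert tau_star(0.002, 0.05, 0.5, 1000) == pytest.approx(0.2)
    assert tau_star(0.002, 0.10, 0.5, 1000) == pytest.approx(0.4)  # homogeneity in sd
    with pytest.raises(ValueError, match="h2"):
        tau_star(0.002, 0.05, 0.0, 1000)


def test_p_positive_tau_star_values():
    assert p_positive_tau_star(0.0, 1.0) == pytest.approx(0.5)
    assert p_positive_tau_star(1.6449, 1.0) == pytest.approx(0.05, abs=1e-4)
    assert p_positive_tau_star(-50.0, 1.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        p_positive_tau_star(1.0, 0.0)


def test_whole_genome_annotation_enrichment_is_one(medium_sim):
    _, panel, _, _, _ = medium_sim
    stack = h.AnnotationStack([h.Annotation("base", np.ones(panel.M), "binary", "baseline")])
    lt = h.ld_scores(panel, stack, h.LdWindow(), adjusted=False)
    chi2 = 1.0 + 50_000 * lt.scores() @ np.array([2e-5])
    res = h.StratifiedHeritabilityModel(
        make_sumstats(panel, np.sqrt(chi2)), lt, stack, config=h.RegressionConfig(weighting="ols")
    ).fit()
    assert res.enrichment["base"] == pytest.approx(1.0)
    assert res.prop_snp["base"] == pytest.approx(1.0)


def test_enrichment_forty_percent_h2_on_ten_percent_snps():
    """An annotation holding 40% of h2 on 10% of SNPs is 4x enriched."""
    rng = np.random.default_rng(9)
    panel = panel_from_arrays(rng.integers(0, 3, size=(200, 1000)).astype(float))
    member = np.zeros(1000)
    member[:100] = 1.0
    stack = h.AnnotationStack(
        [
            h.Annotation("focal", member, "binary"),
            h.Annotation("base", np.ones(1000), "binary", "baseline"),
        ]
    )
    lt = h.ld_scores(panel, stack, h.LdWindow("kb", 1e9), adjusted=False)
    # per-SNP variance: focal SNPs tau_b + tau_f, others tau_b;
    # choose taus so focal holds 40% of total h2 on 10% of SNPs
    tau_b = 1e-5
    # h2(C) = 100*(tau_f + tau_b); h2g = 1000*tau_b + 100*tau_f; want ratio 0.4
    tau_f = (0.4 * 1000 * tau_b - 100 * tau_b) / (100 * (1 - 0.4))
    chi2 = 1.0 + 50_000 * lt.scores() @ np.array([tau_f, tau_b])
    res = h.StratifiedHeritabilityModel(
        make_sumstats(panel, np.sqrt(chi2)), lt, stack, config=h.RegressionConfig(weighting="ols")
    ).fit()
    assert res.prop_h2["focal"] == pytest.approx(0.4, rel=1e-8)
    assert res.enrichment["focal"] == pytest.approx(4.0, rel=1e-8)


def test_degenerate_all_zero_tau_enrichment_flagged(medium_sim):
    _, panel, stack, lt_un, _ = medium_sim
    ss = make_sumstats(panel, np.ones(panel.M))
    res = h.StratifiedHeritabilityModel(
        ss, lt_un, stack, config=h.RegressionConfig(weighting="ols")
    ).fit()
    with pytest.raises(ValueError, match="h2"):
        res.prop_h2  # noqa: B018 - the property itself must raise


def test_partition_conservation():
    """Disjoint binary partition of all SNPs: proportions of h2 sum to 1."""
    rng = np.random.default_rng(10)
    panel = panel_from_arrays(rng.integers(0, 3, size=(100, 600)).astype(float))
    labels = rng.integers(0, 3, size=600)
    stack = h.AnnotationStack(
        [h.Annotation(f"part{k}", (labels == k).astype(float)) for k in range(3)]
    )
    lt = h.ld_scores(panel, stack, h.LdWindow("kb", 1e9), adjusted=False)
    tau_true = np.array([1e-5, 3e-5, 2e-5])
    chi2 = 1.0 + 20_000 * lt.scores() @ tau_true
    res = h.StratifiedHeritabilityModel(
        make_sumstats(panel, np.sqrt(chi2), n=20_000.0),
        lt,
        stack,
        config=h.RegressionConfig(weighting="ols"),
    ).fit()
    assert res.prop_h2.sum() == pytest.approx(1.0, rel=1e-9)


def test_results_from_fit_expose_tau_star_pipeline(medium_sim):
    """tau* from the Results object equals direct evaluation of its formula."""
    _, panel, stack, lt_un, _ = medium_sim
    tau_true = np.array([4e-5, 1e-5])
    chi2 = 1.0 + 50_000 * lt_un.scores() @ tau_true
    res = h.StratifiedHeritabilityModel(
        make_sumstats(panel, np.sqrt(chi2)), lt_un, stack,
        config=h.RegressionConfig(weighting="ols"),
    ).fit()
    for name in stack.names:
        direct = tau_star(res.tau[name], stack[name].sd, res.h2g, panel.M)
        assert res.tau_star[name] == pytest.approx(direct, rel=1e-12)
    assert "tau_star" in res.summary()


def test_two_part_weighting_runs_and_is_consistent(medium_sim):
    _, panel, stack, lt_un, lt_adj = medium_sim
    tau_true = np.array([4e-5, 1e-5])
    ss = h.simulate_sumstats(panel, stack, tau_true, 50_000, seed=5, ldscore_table=lt_un)
    res = h.StratifiedHeritabilityModel(ss, lt_adj, stack).fit()
    assert np.isfinite(res.tau.to_numpy()).all()
    # weighted point estimate in the right neighbourhood of the truth
    assert abs(res.tau["focal"] - tau_true[0]) < 4 * res.tau_se["focal"]
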