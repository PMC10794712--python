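import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import h2scan as h


# ---------------------------------------------------------------------------
# panel generator
# ---------------------------------------------------------------------------

def within_block_correlations(panel):
    """Mean pairwise genotype correlation within realized LD blocks."""
    x = panel.standardized()
    n = panel.n_samples
    rs = []
    for _, grp in panel.snps.groupby("block"):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            continue
        c = (x[:, idx].T @ x[:, idx]) / n
        rs.extend(c[np.triu_indices(len(idx), k=1)])
    return np.asarray(rs)


def test_panel_determinism():
    cfg = h.SimConfig(seed=41, n_snps=300, n_samples=100)
    a = h.simulate_panel(cfg)
    b = h.simulate_panel(cfg)
    assert np.array_equal(a.genotypes, b.genotypes)
    pd.testing.assert_frame_equal(a.snps, b.snps)


def test_independent_snps_have_near_zero_r2():
    cfg = h.SimConfig(seed=42, n_snps=400, n_samples=200, within_block_r=0.0)
    panel = h.simulate_panel(cfg)
    r = within_block_correlations(panel)
    # E[r^2] under independence is ~1/n
    assert 0.5 / 200 < np.mean(r**2) < 2.0 / 200


def test_block_correlation_hits_target():
    cfg = h.SimConfig(seed=43, n_snps=100, n_samples=5000, block_size=5, within_block_r=0.8)
    panel = h.simulate_panel(cfg)
    r = within_block_correlations(panel)
    assert 0.75 < r.mean() < 0.85


def test_across_block_correlation_near_zero():
    cfg = h.SimConfig(seed=44, n_snps=200, n_samples=2000, block_size=10)
    panel = h.simulate_panel(cfg)
    x = panel.standardized()
    blocks = panel.snps["block"].to_numpy()
    rng = np.random.default_rng(0)
    vals = []
    for _ in range(300):
        j, k = rng.integers(0, panel.M, 2)
        if blocks[j] != blocks[k]:
            vals.append((x[:, j] @ x[:, k]) / panel.n_samples)
    assert abs(np.mean(vals)) < 0.01


def test_cm_positions_isolate_blocks():
    cfg = h.SimConfig(seed=45, n_snps=120, n_samples=50)
    panel = h.simulate_panel(cfg)
    cm = panel.snps["cm"].to_numpy()
    blocks = panel.snps["block"].to_numpy()
    # default 1 cM window never reaches an adjacent block
    for b in np.unique(blocks)[:-1]:
        assert cm[blocks == b + 1].min() - cm[blocks == b].max() > 1.0


def test_invalid_block_r_rejected():
    with pytest.raises(ValueError, match="within_block_r"):
        h.SimConfig(within_block_r=1.0)


# ---------------------------------------------------------------------------
# annotation generator
# ---------------------------------------------------------------------------

def test_annotation_coverage_within_binomial_bounds():
    panel = h.simulate_panel(h.SimConfig(seed=46, n_snps=10_000, n_samples=20))
    stack = h.simulate_annotations(panel, [h.AnnotationSpec("a", 0.1)], seed=46)
    lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.1)
    assert lo <= stack["a"].values.sum() <= hi


def test_full_coverage_and_probabilistic_range():
    panel = h.simulate_panel(h.SimConfig(seed=47, n_snps=500, n_samples=20))
    stack = h.simulate_annotations(
        panel,
        [h.AnnotationSpec("all", 1.0), h.AnnotationSpec("p", 0.5, "probabilistic")],
        seed=47,
    )
    assert stack["all"].values.all()
    v = stack["p"].values
    assert (v >= 0).all() and (v <= 1).all() and (v > 0).any()
    assert stack["base"].values.all()  # implicit all-ones base


def test_bad_coverage_rejected():
    panel = h.simulate_panel(h.SimConfig(seed=48, n_snps=50, n_samples=20))
    with pytest.raises(ValueError, match="coverage"):
        h.simulate_annotations(panel, [h.AnnotationSpec("a", 0.0)], seed=48)


# ---------------------------------------------------------------------------
# sumstats generator
# ---------------------------------------------------------------------------

def test_null_mean_chi2_is_one():
    panel = h.simulate_panel(h.SimConfig(seed=49, n_snps=10_000, n_samples=100))
    stack = h.simulate_annotations(panel, [h.AnnotationSpec("a", 0.1)], seed=49)
    ss = h.simulate_sumstats(panel, stack, np.zeros(2), 50_000, seed=49)
    assert abs(ss.chi2.mean() - 1.0) < 3 * np.sqrt(2 / 10_000)


def test_sumstats_deterministic(medium_sim):
    _, panel, stack, lt_un, _ = medium_sim
    tau = np.array([1e-5, 1e-5])
    a = h.simulate_sumstats(panel, stack, tau, 50_000, seed=50, ldscore_table=lt_un)
    b = h.simulate_sumstats(panel, stack, tau, 50_000, seed=50, ldscore_table=lt_un)
    assert np.array_equal(a.z, b.z)
    c = h.simulate_sumstats(panel, stack, tau, 50_000, seed=51, ldscore_table=lt_un)
    assert not np.array_equal(a.z, c.z)


def test_mean_chi2_matches_model_expectation(medium_sim):
    _, panel, stack, lt_un, _ = medium_sim
    tau = np.array([2e-5, 1e-5])
    expect = 1.0 + 50_000 * (lt_un.scores() @ tau)
    reps = [
        h.simulate_sumstats(panel, stack, tau, 50_000, seed=s, ldscore_table=lt_un).chi2
        for s in range(60)
    ]
    mean = np.mean(reps, axis=0)
    # averaged over SNPs the realized mean tracks the model expectation
    assert np.mean(mean) == pytest.approx(np.mean(expect), rel=0.05)


def test_tau_for_tau_star_solves_the_scaling():
    panel = h.simulate_panel(h.SimConfig(seed=52, n_snps=1000, n_samples=50))
    stack = h.simulate_annotations(panel, [h.AnnotationSpec("f", 0.1)], seed=52)
    focal = stack["f"]
    tau_b = 0.05 / panel.M
    tau_f = h.tau_for_tau_star(focal, tau_b, panel.M, 1.0)
    h2g = panel.M * tau_b + focal.values.sum() * tau_f
    assert tau_f * focal.sd / (h2g / panel.M) == pytest.approx(1.0)


def test_ld_correlated_noise_keeps_marginal_moments(medium_sim):
    _, panel, stack, lt_un, _ = medium_sim
    tau = np.array([0.0, 0.0])
    reps = [
        h.simulate_sumstats(panel, stack, tau, 50_000, seed=s, ldscore_table=lt_un,
                            ld_noise=True).chi2
        for s in range(40)
    ]
    mean = np.mean([r.mean() for r in reps])
    assert mean == pytest.approx(1.0, abs=0.05)
    # z-scores of neighbouring SNPs are positively correlated across draws
    z = np.array([
        h.simulate_sumstats(panel, stack, tau, 50_000, seed=s, ldscore_table=lt_un,
                            ld_noise=True).z
        for s in range(40)
    ])
    adj = np.mean([np.corrcoef(z[:, j], z[:, j + 1])[0, 1] for j in range(0, 100, 20)])
    assert adj > 0.1


def test_negative_chi2_variance_rejected(medium_sim):
    _, panel, stack, lt_un, _ = medium_sim
    with pytest.raises(ValueError, match="variance"):
        with pytest.warns(UserWarning):
            h.simulate_sumstats(panel, stack, np.array([-1e-2, 0.0]), 50_000,
                                ldscore_table=lt_un)


# ---------------------------------------------------------------------------
# expression and intervals generators
# ---------------------------------------------------------------------------

def test_expression_deterministic_and_marker_null():
    cfg = h.SimConfig(seed=53, n_cells=400, n_genes=100, n_celltypes=2, marker_fold=1.0)
    with pytest.warns(UserWarning, match="marker_fold"):
        a, truth = h.simulate_expression(cfg)
    with pytest.warns(UserWarning, match="marker_fold"):
        b, _ = h.simulate_expression(cfg)
    assert (a.X != b.X).nnz == 0
    # fold 1: marker scores show no systematic elevation over non-markers
    scores = h.specific_expression_scores(h.normalize_expression(a))
    vals, others = [], []
    for ct in scores.celltypes:
        markers = truth.loc[truth["celltype"] == ct, "gene"]
        in_univ = [g for g in markers if g in scores.genes]
        vals.extend(scores.scores.loc[in_univ, ct])
        rest = scores.genes.difference(markers)
        others.extend(scores.scores.loc[rest, ct])
    p = stats.mannwhitneyu(vals, others, alternative="greater").pvalue
    assert p > 0.01


def test_interval_generator_properties():
    cfg = h.SimConfig(seed=54, n_snps=2000, n_samples=50, peak_coverage=0.2)
    panel = h.simulate_panel(cfg)
    peaks, links, genes = h.simulate_intervals(panel, cfg)
    ann = h.peaks_to_annotation(peaks[0], panel)
    lo, hi = stats.binom.ppf([0.005, 0.995], panel.M, 0.2)
    assert lo <= ann.values.sum() <= hi
    # genes tile the panel; every link belongs to a tiled gene
    assert set(links.table["gene"]) <= set(genes["gene"])
    # deterministic under the seed
    peaks2, links2, genes2 = h.simulate_intervals(panel, cfg)
    pd.testing.assert_frame_equal(links.table, links2.table)
    pd.testing.assert_frame_equal(genes, genes2)
    assert np.array_equal(
        h.peaks_to_annotation(peaks2[0], panel).values, ann.values
    )


def test_no_linked_genes_gives_zero_annotations():
    cfg = h.SimConfig(seed=55, n_snps=200, n_samples=50)
    panel = h.simulate_panel(cfg)
    scores = h.GeneScoreMatrix(
        scores=pd.DataFrame({"ct": [0.5]}, index=["gX"]),
        pvalues=pd.DataFrame({"ct": [0.1]}, index=["gX"]),
    )
    empty = h.Intervals(pd.DataFrame(columns=["chrom", "start", "end", "gene"]))
    (ann,) = h.link_snps(scores, panel, links=empty)
    assert not ann.values.any()


# ---------------------------------------------------------------------------
# fixture directory
# ---------------------------------------------------------------------------

def test_fixture_directory_round_trips(tmp_path):
    cfg = h.SimConfig(seed=56, n_snps=600, n_samples=120, n_traits=2)
    truth = h.write_fixture(cfg, tmp_path)
    panel = h.read_panel(tmp_path / "panel", maf_min=0.0)
    assert panel.M == 600
    ss = h.read_sumstats(tmp_path / "sumstats" / "trait_01.sumstats")
    assert len(ss) == 600
    saved = json.loads((tmp_path / "truth.json").read_text())
    assert saved["planted_celltype"] == truth["planted_celltype"] == "ct01"
    beds = sorted(p.name for p in (tmp_path / "peaks").glob("*.bed"))
    assert beds == ["ct01.bed", "ct02.bed", "ct03.bed"]
    # identical config regenerates identical files
    other = tmp_path / "again"
    h.write_fixture(cfg, other)
    assert (other / "panel.geno.txt").read_bytes() == (tmp_path / "panel.geno.txt").read_bytes()
    assert (other / "sumstats" / "trait_01.sumstats").read_bytes() == (
        tmp_path / "sumstats" / "trait_01.sumstats"
    ).read_bytes()
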