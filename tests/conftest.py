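import numpy as np
import pandas as pd
import pytest

import h2scan as h


def panel_from_arrays(genotypes, chrom=None, pos=None, cm=None, snp_ids=None):
    """Build a SnpPanel directly from a samples x SNPs array."""
    genotypes = np.asarray(genotypes, dtype=float)
    m = genotypes.shape[1]
    freq = np.nanmean(genotypes, axis=0) / 2
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids if snp_ids is not None else [f"rs{i + 1}" for i in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else 1 + np.arange(m) * 100,
            "cm": cm if cm is not None else np.arange(m) * 0.001,
            "a1": "A",
            "a2": "G",
            "maf": np.minimum(freq, 1 - freq),
        }
    )
    return h.SnpPanel(snps=snps, genotypes=genotypes)


@pytest.fixture(scope="session")
def small_panel():
    """40-SNP, 120-sample LD-block panel shared across read-only tests."""
    return h.simulate_panel(h.SimConfig(seed=7, n_snps=40, n_samples=120, block_size=5))


@pytest.fixture(scope="session")
def medium_sim():
    """Panel + annotation stack + LD scores reused by regression tests."""
    cfg = h.SimConfig(seed=11, n_snps=2000, n_samples=500)
    panel = h.simulate_panel(cfg)
    stack = h.simulate_annotations(
        panel, [h.AnnotationSpec("focal", 0.1)], seed=11
    )
    lt_unadj = h.ld_scores(panel, stack, h.LdWindow(), adjusted=False)
    lt_adj = h.ld_scores(panel, stack, h.LdWindow(), adjusted=True)
    return cfg, panel, stack, lt_unadj, lt_adj
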