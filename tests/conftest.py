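"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from culmat.synthetic_panel import SimulationConfig, simulate_panel


def wc_fst(allele_indicators: np.ndarray, labels: np.ndarray) -> float:
    """Weir–Cockerham theta for haploid-equivalent data (ANOVA estimator).

    ``allele_indicators`` is accessions x loci in {0,1} (inbred dosage/2);
    ``labels`` assigns each accession to a discrete population.  Variance
    components are accumulated over loci as a ratio of sums.
    """
    x = np.asarray(allele_indicators, float)
    labels = np.asarray(labels)
    pops = np.unique(labels)
    n_k = np.array([(labels == k).sum() for k in pops], float)
    r = len(pops)
    N = n_k.sum()
    p_k = np.vstack([x[labels == k].mean(axis=0) for k in pops])  # r x m
    pbar = (n_k[:, None] * p_k).sum(axis=0) / N
    msb = (n_k[:, None] * (p_k - pbar) ** 2).sum(axis=0) / (r - 1)
    msw = (n_k[:, None] * p_k * (1 - p_k)).sum(axis=0) / (N - r)
    nc = (N - (n_k**2).sum() / N) / (r - 1)
    a = (msb - msw) / nc
    return float(a.sum() / (a + msw).sum())


@pytest.fixture(scope="session")
def small_panel():
    """A modest structured panel with one planted causal SNP, shared read-only."""
    cfg = SimulationConfig(
        seed=7,
        n_accessions=60,
        n_snps=400,
        n_unigenes=200,
        causal_snps=[(10, 1.5)],
        depth_mean=20.0,
    )
    return simulate_panel(cfg)
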