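"""Shared fixtures: small seeded synthetic cohorts reused across tests."""

import numpy as np
import pytest

from famspec import BRRRConfig, FamilyDesign, synthesize_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """100 sib-pair families, 60 features, familial share 0.5, 2 planted SNPs."""
    return synthesize_cohort(
        n_families=100, sibs_per_family=2, n_snps=20, p_features=60,
        k_true=6, familial_share=0.5, noise_sd=0.1,
        n_causal=2, target_ptve=0.03, seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """30 sib-pair families, 30 features; for cheap structural checks."""
    return synthesize_cohort(
        n_families=30, sibs_per_family=2, n_snps=10, p_features=30,
        k_true=3, familial_share=0.5, noise_sd=0.1, n_causal=0, seed=7,
    )


@pytest.fixture(scope="session")
def light_config():
    """Short Gibbs chain for tests that only need structure, not precision."""
    return BRRRConfig(K=4, n_iter=80, burn_in=40, seed=1)


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """One full-length family-covariate fit on the small cohort."""
    from famspec import fit

    Y, F, G, truth = small_cohort
    post = fit(Y, F.indicator, BRRRConfig(K=6, n_iter=200, burn_in=100, seed=5))
    return post
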