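import numpy as np
import pandas as pd
import pytest

from crcith.cohort import CohortConfig, simulate_cohort
from crcith.normalize import filter_expressed, log2_cpm, tmm_factors


def normalize_cohort(cohort, threshold=1.0):
    """Standard normalization chain used across the tests."""
    factors = tmm_factors(cohort.counts)
    expr = log2_cpm(cohort.counts, factors)
    return filter_expressed(expr, threshold, cohort.gene_meta["coding"])


@pytest.fixture(scope="session")
def small_cohort():
    """Four tumors x three biopsies in the shared gene universe."""
    return simulate_cohort(CohortConfig(n_tumors=4, seed=7, gene_seed=0))


@pytest.fixture(scope="session")
def default_cohort():
    """The default 14 x 3 study-scale cohort."""
    return simulate_cohort(CohortConfig(seed=3, gene_seed=0))


@pytest.fixture(scope="session")
def default_expr(default_cohort):
    return normalize_cohort(default_cohort)


@pytest.fixture(scope="session")
def trained_classifiers():
    """Both classifier families trained on an independent labeled cohort."""
    from crcith.classify import KTSPSubtyper, NearestCentroidSubtyper
    from crcith.pipeline import intrinsic_gene_mask

    cohort = simulate_cohort(
        CohortConfig(seed=11, n_tumors=100, biopsies_per_tumor=2,
                     replicate=1, gene_seed=0)
    )
    expr = normalize_cohort(cohort)
    labels = pd.Series(cohort.truth.subtype)[expr.columns]
    ssp = NearestCentroidSubtyper(classifier_id="SSP").fit(expr.T, labels)
    mask = intrinsic_gene_mask(cohort.gene_meta).reindex(expr.index)
    expr_i = expr.loc[mask[mask].index]
    ktsp = KTSPSubtyper(classifier_id="kTSP").fit(expr_i.T, labels)
    return ssp, ktsp


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
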