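import warnings

import pytest

from sepsisprot import SimConfig, generate_clinical, generate_cohort, generate_gene_sets


@pytest.fixture(scope="session")
def default_cohort():
    """Default-size synthetic cohort (23+23, 120 proteins) with clinical data."""
    cfg = SimConfig(seed=7)
    matrix, records, truth = generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = generate_clinical(truth, records, cfg, matrix)
    gene_sets = generate_gene_sets(cfg, truth)
    return cfg, matrix, records, truth, gene_sets


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast cohort for I/O and plumbing tests."""
    cfg = SimConfig(n_sepsis=6, n_control=6, n_proteins=15, n_dep=4,
                    n_outcome_proteins=2, n_mortality_proteins=2,
                    n_terms=6, term_size_range=(3, 8), enriched_terms=2, seed=11)
    matrix, records, truth = generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = generate_clinical(truth, records, cfg, matrix)
    gene_sets = generate_gene_sets(cfg, truth)
    return cfg, matrix, records, truth, gene_sets
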