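import numpy as np
import pytest

from ebfine import (
    block_ld_profile,
    make_haplotype_panel,
    simulate_case_control,
    summarize_all,
)


@pytest.fixture(scope="session")
def small_panel():
    """40-SNP block-LD panel with the causal site pinned at MAF 0.18."""
    mafs = np.random.default_rng(7).uniform(0.05, 0.5, 40)
    mafs[20] = 0.18
    return make_haplotype_panel(
        400,
        40,
        maf_sampler=mafs,
        ld_profile=block_ld_profile(40, 8, 0.9),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_panel):
    """600 cases + 600 controls, causal SNP 20, per-allele OR 1.4."""
    return simulate_case_control(small_panel, 20, 1.4, 600, 600, seed=11)


@pytest.fixture(scope="session")
def small_summaries(small_dataset):
    return summarize_all(small_dataset)
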