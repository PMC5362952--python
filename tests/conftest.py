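import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from armloy import synthcohort
from armloy.genome import build_genome

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


TOY_GENOME_CONFIG = {
    "bin_size": 5000,
    "chromosomes": [
        {"name": "chr1", "length": 5_000_000, "centromere": 2_500_000},
        {"name": "chr2", "length": 5_000_000, "centromere": 2_000_000},
        {"name": "chr3", "length": 4_000_000, "centromere": 2_000_000},
        {"name": "chrX", "length": 3_000_000, "centromere": 1_500_000},
        {"name": "chrY", "length": 2_500_000},
    ],
}


@pytest.fixture(scope="session")
def toy_genome():
    """Miniature five-chromosome karyotype: 400-500 bins per arm, 500 on
    chrY — enough for arm medians to concentrate, small enough to be fast."""
    return build_genome(TOY_GENOME_CONFIG)


def male_pair_cohort(n=30, n_loy=8, lo=0.2, hi=0.75, **extra):
    cfg = dict(
        n_male=n,
        n_female=0,
        tissues=["tumor", "normal"],
        lam=30.0,
        events=[
            dict(arm="chrY", kind="loss", tissue="tumor", n=n_loy,
                 fraction_range=(lo, hi)),
        ],
    )
    cfg.update(extra)
    return cfg


@pytest.fixture(scope="session")
def loy_cohort(toy_genome):
    """30 male tumor/normal pairs, 8 tumors with planted LOY, seed 7."""
    truth = synthcohort.plant_events(male_pair_cohort(), 7)
    covset = synthcohort.simulate_bin_counts(truth, toy_genome)
    return truth, covset
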