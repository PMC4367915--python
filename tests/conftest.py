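import numpy as np
import pandas as pd
import pytest

from medipdiff import SyntheticConfig, simulate_experiment
from medipdiff.profiles import FragmentSet


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_chromosomes=2,
        chrom_length=150_000,
        n_genes=10,
        n_repeats_per_class=5,
        n_fragments=20_000,
        n_planted_dmrs=10,
        planted_fold=4.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def experiment(small_config):
    """One shared synthetic experiment; fixture-scoped, never mutated."""
    return simulate_experiment(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_fragments(rows, sample="S"):
    """Build a FragmentSet from (chrom, start, end[, unique]) tuples."""
    recs = []
    for row in rows:
        chrom, start, end = row[:3]
        unique = row[3] if len(row) > 3 else True
        recs.append({"chrom": chrom, "start": start, "end": end, "unique": unique})
    return FragmentSet(sample, pd.DataFrame(recs))


def uniform_1bp_fragments(chrom, length, sample="S"):
    """Deterministic 1x coverage: one 1-bp fragment at every position."""
    starts = np.arange(length)
    return FragmentSet(
        sample,
        pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": starts + 1, "unique": True}
        ),
    )
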