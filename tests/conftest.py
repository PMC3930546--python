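import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import triadscan as ts

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> ts.SimulatedCohort:
    """A 174-sample cohort small enough for fast module tests."""
    return ts.simulate_cohort(ts.SimulationConfig(n_snps=150, n_probesets=12, seed=42))


@pytest.fixture(scope="session")
def tiny_cohort() -> ts.SimulatedCohort:
    """A reduced-sample cohort for pipeline-level tests."""
    cfg = ts.SimulationConfig(
        n_per_population=(20, 18, 20), n_snps=80, n_probesets=10, seed=7
    )
    return ts.simulate_cohort(cfg)


def random_scan_table(rng: np.random.Generator, n_snps: int) -> pd.DataFrame:
    """A randomized association table with clustered significant SNPs."""
    chrom = rng.integers(1, 5, size=n_snps).astype(str)
    pos = rng.integers(1, 2_000_000, size=n_snps)
    p = 10.0 ** rng.uniform(-7, 0, size=n_snps)
    # push most SNPs toward null so significant ones cluster realistically
    null = rng.random(n_snps) < 0.7
    p[null] = rng.uniform(0.001, 1.0, size=null.sum())
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": pos,
            "p": p,
            "r": rng.uniform(-0.5, 0.5, size=n_snps),
        }
    )
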