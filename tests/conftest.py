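import numpy as np
import pandas as pd
import pytest

from twostepmr import SimParams, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A reduced but complete synthetic study: three cohorts, three mediators
    (two causal, one null), a mediator SNP panel with LD blocks, and a
    disjoint outcome sample."""
    params = SimParams(
        n_individuals=(300, 400, 250),
        n_mediators=3,
        theta=(0.4, 0.4, 0.0),
        # instrument strength scaled up so first-stage F at these reduced
        # cohort sizes matches the strong-instrument regime of the full design
        exposure_h2=0.15,
        n_mediator_snps=12,
        mediator_h2=0.3,
        ld_block_size=3,
        ld_within_block_r2=0.3,
        n_outcome_individuals=3000,
        log_or_per_sd=float(np.log(1.3)),
        seed=7,
    )
    return simulate_study(params)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_gwas_table(rows):
    """Build a GWAS summary-statistics frame from (SNP, EA, OA, EAF, BETA, SE, P, N) tuples."""
    return pd.DataFrame(rows, columns=["SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"])
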