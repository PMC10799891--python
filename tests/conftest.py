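import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_call_tables():
    """Three pseudo-tool call tables over 5 samples, built to exercise
    every branch of the consensus filter truth table."""
    samples = [f"s{i}" for i in range(5)]

    def table(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", *samples])

    # jA: called by 3 tools, counts {2,2,0,0,0} -> retained
    # jB: called by 3 tools, counts {3,0,0,0,0} -> only one individual >=2 -> removed
    # jC: called by 1 tool only -> removed regardless of counts
    # jD: called by 2 tools, abundant in only one of them -> retained
    jA = ["chr1", 100, 500, "+"]
    jB = ["chr1", 700, 900, "+"]
    jC = ["chr2", 10, 90, "-"]
    jD = ["chr2", 200, 400, "+"]
    return {
        "toolA": table([jA + [2, 2, 0, 0, 0], jB + [3, 0, 0, 0, 0], jD + [0, 1, 0, 0, 0]]),
        "toolB": table([jA + [2, 2, 0, 0, 0], jB + [3, 0, 0, 0, 0], jD + [5, 5, 5, 0, 0]]),
        "toolC": table([jA + [2, 2, 0, 0, 0], jB + [3, 0, 0, 0, 0], jC + [9, 9, 9, 9, 9]]),
    }


@pytest.fixture(scope="session")
def null_cohort():
    """A moderate null cohort (no effects) reused across tests."""
    from circimbalance.synthetic_cohort import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_cases=40,
        n_controls=40,
        n_genes=400,
        n_bsj=100,
        global_circ_log2fc=0.0,
        de_gene_fraction=0.0,
        batch_log2fc=0.0,
        seed=101,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
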