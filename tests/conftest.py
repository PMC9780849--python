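import numpy as np
import pandas as pd
import pytest

from msreseq import SimulationConfig, make_design, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One-chromosome cohort (~5k sites) with planted site effects."""
    cfg = SimulationConfig(seed=7, chrom_spec=(("chr1", 7_000_000),),
                           baseline_beta=(5, 15), delta=1.1)
    return simulate_cohort(cfg, conditions=("MB",))


@pytest.fixture
def design_6v6():
    return make_design(6, "MB")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def two_group_vector(control, cp, condition="MB"):
    """Score vector + matching design for hand-built LRT examples,
    control samples first."""
    design = make_design(max(len(control), len(cp)), condition)
    design = pd.concat([
        design[design["group"] == "control"].iloc[:len(control)],
        design[design["group"] == "CP"].iloc[:len(cp)],
    ]).reset_index(drop=True)
    y = np.array(list(control) + list(cp), dtype=float)
    return y, design
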