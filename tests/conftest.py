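import numpy as np
import pandas as pd
import pytest

from hic3state.simulate import (
    SimulationConfig,
    make_ground_truth,
    simulate_annotations,
    simulate_contact_matrix,
    simulate_expression,
)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimulationConfig:
    """One 4 Mb chromosome, 5 TADs, a handful of loops: fast enough for
    per-module tests while exercising every planted structure."""
    return SimulationConfig(
        n_chroms=1,
        chrom_length=4_000_000,
        n_tads_per_chrom=5,
        n_split_tads_per_chrom=1,
        n_common_loops_per_chrom=2,
        n_normal_loops_per_chrom=1,
        n_cancer_loops_per_chrom=2,
        depth=400_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_cfg):
    return make_ground_truth(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_cfg, tiny_truth):
    return simulate_contact_matrix(tiny_cfg, tiny_truth, "normal")


@pytest.fixture(scope="session")
def tiny_annotations(tiny_cfg, tiny_truth):
    return {
        cond: simulate_annotations(tiny_cfg, tiny_truth, cond)
        for cond in tiny_cfg.conditions
    }


@pytest.fixture(scope="session")
def tiny_expression(tiny_cfg, tiny_truth):
    return simulate_expression(tiny_cfg, tiny_truth)


def intervals_df(rows) -> pd.DataFrame:
    """(chrom, start, end[, name[, score]]) tuples -> interval frame."""
    cols = ["chrom", "start", "end", "name", "score"]
    return pd.DataFrame([dict(zip(cols, r)) for r in rows])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_923)
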