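import numpy as np
import pandas as pd
import pytest

from tfsilence.synthetic_cohort import CohortConfig, generate_cohort
from tfsilence.workflow import run_pipeline


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort for fast structural tests."""
    return CohortConfig(
        seed=7, n_genes=300, n_tfs=40, n_housekeeping=30, n_tissues=2,
        cancers_per_tissue=(1, 1), n_hesc=8, n_normal_tissue=3,
        n_normal_adjacent=10, n_tumour=24, n_chromosomes=4,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default study conditions, seed 1."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_cohort):
    return run_pipeline(default_cohort, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_diff_table(t_values: dict[str, float],
                    p_values: dict[str, float] | None = None) -> pd.DataFrame:
    """Hand-build a moderated-t table for pipeline unit tests."""
    genes = list(t_values)
    t = np.array([t_values[g] for g in genes])
    if p_values is None:
        from scipy import stats as sps
        p = 2 * sps.norm.sf(np.abs(t))
    else:
        p = np.array([p_values[g] for g in genes])
    from tfsilence.stats import bh_adjust
    return pd.DataFrame({"log2_fc": t * 0.3, "t_mod": t, "p": p,
                         "p_adj": bh_adjust(p),
                         "df_total": np.full(len(genes), 30.0)}, index=genes)
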