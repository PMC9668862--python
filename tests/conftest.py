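import numpy as np
import pandas as pd
import pytest

from crossmark.profiles import CohortProfile
from crossmark.simulate import default_config, generate_cohorts


@pytest.fixture(scope="session")
def small_run():
    """A reduced 4-cohort dataset for fast structural tests."""
    cfg = default_config(
        seed=7, n_cohorts=4, n_genera=58, n_core_genera=50,
        samples_per_group={"HC": 15, "CA": 15, "CRC": 15},
    )
    profiles, truth = generate_cohorts(cfg)
    return cfg, profiles, truth


@pytest.fixture(scope="session")
def default_run():
    """One draw of the full default study preset (6 cohorts, 30/group)."""
    cfg = default_config(seed=11)
    profiles, truth = generate_cohorts(cfg)
    return cfg, profiles, truth


@pytest.fixture(scope="session")
def default_sweep():
    """Ten seed-swept draws of the default preset, generated lazily once."""
    out = {}
    for seed in range(10):
        cfg = default_config(seed=seed)
        out[seed] = (cfg,) + generate_cohorts(cfg)
    return out


def make_profile(values, groups=None, cohort_id="c1", taxa=None):
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    sids = [f"s{i}" for i in range(n)]
    taxa = taxa or [f"T{j}" for j in range(t)]
    md = None
    if groups is not None:
        md = pd.DataFrame({"group": list(groups)}, index=sids)
    return CohortProfile(cohort_id, pd.DataFrame(values, index=sids, columns=taxa), md)


@pytest.fixture
def two_group_profile():
    rng = np.random.default_rng(0)
    x = rng.dirichlet(np.ones(5), size=12)
    return make_profile(x, groups=["HC"] * 6 + ["CRC"] * 6)
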