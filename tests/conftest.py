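import numpy as np
import pandas as pd
import pytest

from cardiogrs.panel import load_panel, grs14_subset, load_raf_table
from cardiogrs.simulate import afro_caribbean_config, simulate_case_control


@pytest.fixture(scope="session")
def panel19():
    return load_panel("grs19")


@pytest.fixture(scope="session")
def panel14(panel19):
    return grs14_subset(panel19)


@pytest.fixture(scope="session")
def afro_rafs(panel19):
    tbl = load_raf_table("afro_caribbean_controls")
    return {r: float(tbl.loc[r, "raf"]) for r in panel19.rsids}


@pytest.fixture(scope="session")
def white_rafs(panel19):
    tbl = load_raf_table("white_controls")
    return {r: float(tbl.loc[r, "raf"]) for r in panel19.rsids}


@pytest.fixture(scope="session")
def small_cohort():
    """A fast study-structured cohort: 60 cases / 120 controls."""
    cfg = afro_caribbean_config(seed=7)
    cfg.n_cases, cfg.n_controls = 60, 120
    cfg.superpopulation_size = 2500
    return simulate_case_control(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
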