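import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import spathet as sp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def markers():
    return sp.default_marker_panel().markers


@pytest.fixture(scope="session")
def hallmarks():
    return sp.default_hallmark_sets()


def make_table(n=20, markers=("A", "B"), seed=0, sample_id="s1"):
    """Small random single-sample cell table for unit tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "cell_id": [f"{sample_id}_c{i}" for i in range(n)],
            "sample_id": sample_id,
            "x": rng.uniform(0, 100, n),
            "y": rng.uniform(0, 100, n),
            "area": rng.uniform(50, 150, n),
            "quality_score": rng.uniform(0, 1, n),
        }
    )
    for m in markers:
        df[m] = rng.lognormal(5, 1, n)
    return sp.CellTable(df=df, markers=tuple(markers))


@pytest.fixture
def simple_table():
    return make_table()


@pytest.fixture(scope="session")
def small_cohort():
    """3-vs-3 default-design cohort at 400 cells per sample."""
    cfg = sp.default_config(n_subjects_per_group=3, cells_per_sample=400, seed=7)
    tables, meta = sp.generate_cohort(cfg)
    return cfg, tables, meta


def pool_tables(tables):
    ts = list(tables.values()) if isinstance(tables, dict) else list(tables)
    df = pd.concat([t.df for t in ts], ignore_index=True)
    return sp.CellTable(df=df, markers=ts[0].markers)
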