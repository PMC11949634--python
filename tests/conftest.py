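"""Shared fixtures: a small synthetic cohort reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from igc_induction import GeneratorConfig, build_event_panel, generate_dataset, load_tables

SMALL_CFG = dict(
    cohort_sizes=(8, 8, 8),
    n_days=60,
    igc_rate=0.5,
    agonism_rate=3.0,
    seed=42,
)


@pytest.fixture(scope="session")
def small_dir(tmp_path_factory):
    """Directory with a small generated dataset (written once per session)."""
    out = tmp_path_factory.mktemp("cohort")
    generate_dataset(GeneratorConfig(**SMALL_CFG), out_dir=out)
    return out


@pytest.fixture(scope="session")
def small_dataset(small_dir):
    return load_tables(small_dir)


@pytest.fixture(scope="session")
def small_panel(small_dataset):
    return build_event_panel(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_roster(n: int, group: str = "G1", adults: int = 0) -> pd.DataFrame:
    """Minimal roster of ``n`` non-adults (+ optional adults) in one group."""
    rows = []
    for j in range(adults):
        rows.append({"id": f"{group}A{j:02d}", "sex": "F", "birth_date": -3000,
                     "mother_id": "", "group_id": group, "is_adult": True})
    for i in range(n):
        rows.append({"id": f"{group}N{i:02d}", "sex": "F", "birth_date": 0,
                     "mother_id": f"{group}A00" if adults else "",
                     "group_id": group, "is_adult": False})
    return pd.DataFrame(rows)
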