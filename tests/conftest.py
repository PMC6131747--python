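import numpy as np
import pandas as pd
import pytest

from delcal.instruments import InstrumentSpec, Item, ResponseTable, load_bundled_specs
from delcal.pipeline import PipelineConfig, run_pipeline
from delcal.simulate import GeneratorConfig, simulate_study

MODELED = ["DRS-R-98", "MDAS", "CAM-S-long"]


@pytest.fixture(scope="session")
def bundled_specs():
    return load_bundled_specs()


@pytest.fixture(scope="session")
def study():
    """One default synthetic cohort shared across read-only tests."""
    return simulate_study(GeneratorConfig(seed=20240915))


@pytest.fixture(scope="session")
def model(study):
    """One full four-step co-calibration of the default cohort."""
    tables = {k: study.tables[k] for k in MODELED}
    return run_pipeline(tables, study.specs, PipelineConfig())


@pytest.fixture
def toy_spec():
    """A small 2-item polytomous instrument for hand-checkable cases."""
    return InstrumentSpec(
        name="toy",
        items=(
            Item("alpha", "domain_a", 4, 1),
            Item("beta", "domain_b", 3, 2),
        ),
    )


def make_table(name: str, ratings: dict[str, list]) -> ResponseTable:
    n = len(next(iter(ratings.values())))
    data = pd.DataFrame(
        {"person_id": np.arange(1, n + 1), "day": np.ones(n, dtype=int)}
    )
    for item, vals in ratings.items():
        data[item] = np.asarray(vals, dtype=float)
    return ResponseTable(instrument=name, data=data)
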