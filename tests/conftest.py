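import numpy as np
import pandas as pd
import pytest

from vinemet import synth
from vinemet.io import AbundanceTable


@pytest.fixture(scope="session")
def fixture_effects():
    return synth.load_fixture_effects()


@pytest.fixture(scope="session")
def effects_by_name(fixture_effects):
    return {e.metabolite: e for e in fixture_effects}


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (printed effects, n=12, seed 1)."""
    config = synth.default_config(seed=1)
    return config, synth.generate_abundance_table(config)


@pytest.fixture
def tiny_table():
    """Hand-sized 4-sample, 3-metabolite table for container tests."""
    samples = pd.DataFrame(
        {
            "cultivar": ["Cs", "Cs", "Sh", "Sh"],
            "temperature": ["25", "35", "25", "35"],
            "day": ["2", "2", "2", "2"],
            "replicate": ["1", "1", "1", "1"],
        }
    )
    data = pd.DataFrame(
        {
            "Glucose": [10.0, 6.1, 8.0, 3.2],
            "Malate": [5.0, 1.8, 6.0, 3.4],
            "Raffinose": [1.0, 1.8, 1.1, 3.5],
        }
    )
    return AbundanceTable(samples, data)


def make_table(cell_values: dict, metabolites: list[str]) -> AbundanceTable:
    """Build a table from {(cultivar, temperature): 2-D array} blocks."""
    rows, meta = [], []
    for (cultivar, temperature), block in cell_values.items():
        block = np.asarray(block, float)
        for r, row in enumerate(block):
            rows.append(row)
            meta.append(
                {
                    "cultivar": cultivar,
                    "temperature": temperature,
                    "day": str(2 + 2 * (r % 3)),
                    "replicate": str(r + 1),
                }
            )
    samples = pd.DataFrame(meta, columns=["cultivar", "temperature", "day", "replicate"])
    data = pd.DataFrame(np.vstack(rows), columns=metabolites)
    return AbundanceTable(samples, data)
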