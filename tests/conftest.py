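import numpy as np
import pandas as pd
import pytest

from dropletomics.nomenclature import parse_any
from dropletomics.tables_io import AbundanceTable
from dropletomics.synthetic_data import generate, paperlike_preset


def build_table(values: dict[str, list], samples: list[str],
                units: str = "raw",
                design: dict[str, str] | None = None) -> AbundanceTable:
    """Assemble an AbundanceTable from {species name: row values}."""
    keys = {}
    rows = {}
    for name, row in values.items():
        key = parse_any(name)
        keys[str(key)] = key
        rows[str(key)] = [np.nan if v is None else float(v) for v in row]
    data = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    data.index.name = "species"
    return AbundanceTable(data=data, species=keys, units=units,
                          design=design or {})


@pytest.fixture
def make_table():
    return build_table


@pytest.fixture(scope="session")
def preset_dataset():
    """One synthetic study at the default (study-sized) group layout."""
    return generate(paperlike_preset(seed=7))


@pytest.fixture(scope="session")
def two_group_table():
    """A well-separated two-group raw table for PLS/PCA tests."""
    rng = np.random.default_rng(42)
    samples = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
    design = {s: ("GA" if s.startswith("A") else "GB") for s in samples}
    base = rng.uniform(50, 150, size=12)
    values = {}
    for k, c in enumerate(range(40, 64, 2)):
        row = base[k] * np.exp(rng.normal(0, 0.1, size=12))
        if k < 3:  # planted: higher in GA
            row[:6] *= 2.5
        values[f"TG {c}:{k % 4}"] = row.tolist()
    return build_table(values, samples, units="raw", design=design)
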