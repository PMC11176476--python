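import numpy as np
import pandas as pd
import pytest

from recurcor import (
    AUCTable,
    LineageMap,
    SimConfig,
    generate_monotherapy_datasets,
    run_analysis,
)


@pytest.fixture
def toy_tables():
    """Three tiny datasets with a perfectly correlated pair (A, B) and an
    anti-correlated pair (A, C), each dataset on 12 shared cell lines."""
    rng = np.random.default_rng(7)
    lines = [f"cl{i}" for i in range(12)]
    base = rng.normal(size=12)
    tables = []
    for d in range(3):
        rows = []
        for i, cl in enumerate(lines):
            rows.append(("A", cl, 5 + base[i]))
            rows.append(("B", cl, 3 + 2 * base[i]))
            rows.append(("C", cl, 4 - base[i]))
        tables.append(
            AUCTable(f"D{d+1}", pd.DataFrame(rows, columns=["drug", "cell_line", "auc"]))
        )
    return tables


@pytest.fixture
def lineage_map():
    return LineageMap(entries={f"cl{i}": "lung" for i in range(12)})


@pytest.fixture(scope="session")
def sim_bundle():
    """One simulated multi-screen experiment under the default conditions."""
    cfg = SimConfig(seed=11)
    tables, class_map, lineage_map, truth = generate_monotherapy_datasets(cfg)
    return cfg, tables, class_map, lineage_map, truth


@pytest.fixture(scope="session")
def sim_result(sim_bundle):
    _, tables, class_map, lineage_map, _ = sim_bundle
    return run_analysis(tables, class_map, lineage_map)
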