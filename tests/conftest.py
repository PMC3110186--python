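import numpy as np
import pandas as pd
import pytest

from adjx.datatypes import ExpressionDataset
from adjx.simulate import SimulationConfig, simulate_dataset


def make_dataset(values, groups, timepoints, replicates, genes=None):
    """Small helper: build an ExpressionDataset from a 2-D array and
    per-sample metadata lists."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i + 1}" for i in range(n_genes)]
    samples = [f"S{j + 1}" for j in range(n_samples)]
    design = pd.DataFrame(
        {"group": groups, "timepoint_h": timepoints, "replicate": replicates},
        index=samples,
    )
    return ExpressionDataset(pd.DataFrame(values, index=genes, columns=samples), design)


@pytest.fixture(scope="session")
def two_group_config():
    """One treatment/control pair, one timepoint active, modest genome —
    the workhorse config for unit tests."""
    return SimulationConfig(
        n_genes=400,
        groups=(("T", "C"),),
        timepoints_h=(4.0, 24.0, 48.0),
        n_replicates=4,
        de_fraction={("T", 24.0): 0.1},
        effect_size_log2=2.0,
        effect_sd=0.0,
        noise_sd=0.25,
        n_modules=2,
        module_size=30,
        module_r2=0.6,
        n_sets=8,
        set_size=15,
        n_enriched_sets=2,
        graph_hub_degree=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def two_group_sim(two_group_config):
    return simulate_dataset(two_group_config)
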