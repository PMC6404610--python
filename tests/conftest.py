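import numpy as np
import pandas as pd
import pytest

import coexnet as cx


def make_metadata(populations=("ancestor", "control", "heat", "oxidative"),
                  temperatures=(20, 30), n_replicates=6) -> pd.DataFrame:
    rows = []
    for pop in populations:
        for temp in temperatures:
            for rep in range(1, n_replicates + 1):
                rows.append({"sample_id": f"{pop}_{temp}_r{rep}",
                             "population": pop, "temperature": temp,
                             "replicate": rep})
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture(scope="session")
def full_metadata() -> pd.DataFrame:
    return make_metadata()


@pytest.fixture(scope="session")
def small_simulation():
    """A light simulated study shared by read-only tests."""
    design = cx.SimulationDesign(
        modules=[
            cx.module_archetype("SHARED_PLASTICITY", 80),
            cx.module_archetype("EVOLVED_PLASTICITY", 60),
        ],
        n_background_genes=150,
        rng_seed=123,
    )
    counts, meta, truth = cx.simulate_counts(design)
    return design, counts, meta, truth
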