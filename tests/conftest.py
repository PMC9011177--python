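import numpy as np
import pandas as pd
import pytest

import pvburden as pv


@pytest.fixture(scope="session")
def demo_config():
    return pv.default_config(n_individuals=20_000, seed=11)


@pytest.fixture(scope="session")
def demo_sim(demo_config):
    """One moderately sized run of the full demonstration configuration,
    shared across tests: (cohort, calls, truth)."""
    return pv.simulate_cohort(demo_config)


@pytest.fixture(scope="session")
def demo_carriers(demo_config, demo_sim):
    cohort, calls, _ = demo_sim
    return pv.collapse_carriers(calls, demo_config.genes,
                                roster=cohort["individual_id"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def make_calls(rows):
    """Variant-call DataFrame from (individual, gene, variant, class[, founder])."""
    rows = [tuple(r) + (0,) * (5 - len(r)) for r in rows]
    return pd.DataFrame(rows, columns=["individual_id", "gene", "variant_id",
                                       "class", "founder"])
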