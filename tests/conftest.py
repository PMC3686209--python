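import numpy as np
import pandas as pd
import pytest

from seacomp.catalog import CATALOG_COLUMNS, SAMPLE_COLUMNS
from seacomp.simulate import SimConfig, simulate_survey


def make_catalog(rows):
    """Catalog frame from (gene, cluster, genome, ecotype, start, end) tuples,
    or full 10-tuples."""
    full = []
    for r in rows:
        if len(r) == len(CATALOG_COLUMNS):
            full.append(tuple(r))
        else:
            g, c, gen, eco, s, e = r
            full.append((g, c, gen, eco, s, e, "+", True, "", "prochlorococcus"))
    return pd.DataFrame(full, columns=CATALOG_COLUMNS)


def make_samples(rows):
    """Sample sheet from (sample_id, sea[, depth, stratum, library]) tuples."""
    full = []
    for r in rows:
        r = tuple(r) + (25.0, "mixed_layer", 0)[len(r) - 2 :]
        full.append(r)
    return pd.DataFrame(full, columns=SAMPLE_COLUMNS)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_clusters=60, library_size=2000, n_planted=4, seed=11)


@pytest.fixture(scope="session")
def survey(small_config):
    """One small synthetic survey shared by read-level tests."""
    catalog, samples, counts, truth, hits = simulate_survey(small_config)
    return {
        "config": small_config,
        "catalog": catalog,
        "samples": samples,
        "counts": counts,
        "truth": truth,
        "hits": hits,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
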