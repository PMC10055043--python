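import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from zonescape import simulate as sim
from zonescape.annotation import attach_zone_labels


@pytest.fixture(scope="session")
def default_params():
    return sim.SimParams(seed=0)


@pytest.fixture(scope="session")
def tissue(default_params):
    """A medium wild-type tissue reused across read-only tests."""
    return sim.simulate_tissue(default_params, n_cells=1200)


@pytest.fixture(scope="session")
def cko_tissue(default_params):
    return sim.simulate_tissue(
        default_params.with_genotype(sim.NFI_CKO), n_cells=1200
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_gene_table(rng, n, n_chrom=3, with_classI=True):
    """A random but sorted OR gene table for oracle comparisons."""
    chroms = [f"chr{i+1}" for i in rng.integers(0, n_chrom, size=n)]
    starts = rng.integers(0, 3_000_000, size=n)
    lengths = rng.integers(500, 5_000, size=n)
    df = pd.DataFrame({
        "gene_id": [f"G{i:03d}" for i in range(n)],
        "chrom": chroms,
        "start": starts,
        "end": starts + lengths,
        "strand": rng.choice(["+", "-"], size=n),
        "zone_index": rng.uniform(0.75, 5.25, size=n),
        "class_I": rng.random(size=n) < (0.1 if with_classI else 0.0),
    })
    df.loc[df["class_I"].astype(bool), "zone_index"] = 1.0
    df["class_I"] = df["class_I"].astype(int)
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return attach_zone_labels(df)


@pytest.fixture()
def gene_table(rng):
    return random_gene_table(rng, 60)
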