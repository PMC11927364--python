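import numpy as np
import pandas as pd
import pytest

from meioloop import (GenomeLayout, RegionSet, SimulationConfig,
                      simulate_dataset)


@pytest.fixture(scope="session")
def layout5() -> GenomeLayout:
    """Five 4-Mb chromosomes (the default 20 Mb study genome)."""
    return GenomeLayout({f"chr{i + 1}": 4_000_000 for i in range(5)})


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset (50 planted loops on 20 Mb), shared."""
    return simulate_dataset(SimulationConfig(seed=7))


def uniform_regions(layout: GenomeLayout, n: int, width: int,
                    rng: np.random.Generator) -> RegionSet:
    """n regions of fixed width placed uniformly on the layout."""
    chroms = layout.chroms
    lens = np.array([layout.length(c) for c in chroms])
    ci = rng.integers(0, len(chroms), n)
    pos = (rng.random(n) * (lens[ci] - width)).astype(np.int64)
    return RegionSet.from_arrays(np.array(chroms, dtype=object)[ci], pos,
                                 pos + width, layout=layout)


@pytest.fixture(scope="session")
def make_uniform_regions():
    return uniform_regions
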