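import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import reelscan as rs

settings.register_profile(
    "reelscan",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("reelscan")


def make_region(length: int, seed: int = 0, chrom: str = "chrT", start: int = 0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), length))
    return rs.GenomicRegion(chrom, start, start + length, seq)


@pytest.fixture
def region70():
    return make_region(70, seed=1)


@pytest.fixture
def small_libs():
    """Two offset libraries over a 30-tile region."""
    return rs.design_tiling(make_region(35 * 30, seed=2))


@pytest.fixture
def tiny_screen():
    """A small simulated screen: 30 tiles, 5 functional (retention 0.7)."""
    lib, _ = rs.design_tiling(make_region(35 * 30, seed=2))
    f = np.zeros(len(lib))
    f[:5] = 0.3
    model = rs.SelectionModel(f=f, seed=7)
    design = rs.ScreenDesign(depth=50_000, pool_size=200_000)
    cm, truth = rs.simulate_screen(lib, model, design)
    return lib, model, design, cm, truth


@pytest.fixture
def frep_background():
    """Synthetic rejected proteins augmenting the published worked example
    (the eliminated background set is not printed anywhere, so these rows
    are invented for testing the rejection reasons)."""
    return pd.DataFrame(
        {
            "protein": ["HSPA8", "ACTB", "TUBB", "GAPDH", "EEF1A1"],
            "sample1": [5, 7, 0, 0, 3],
            "sample2": [4, 0, 2, 0, 2],
            "control1": [3, 0, 0, 0, 1],
            "control2": [2, 0, 0, 0, 0],
            "element": ["S1606"] * 5,
        }
    )
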