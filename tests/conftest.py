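import numpy as np
import pandas as pd
import pytest

from railmix.panel import PanelSpec
from railmix import simdata


@pytest.fixture(scope="session")
def fixed_panel13() -> PanelSpec:
    """13-locus panel with fixed allele differences (p_king=1, p_clapper=0)."""
    return PanelSpec.fixed_difference(13)


@pytest.fixture(scope="session")
def fixed_panel4() -> PanelSpec:
    return PanelSpec.fixed_difference(4)


@pytest.fixture(scope="session")
def default_panel() -> PanelSpec:
    """Study-like panel: 13 loci, differential mean 0.96, SD 0.08, floor 0.7."""
    return simdata.make_panel(13, mean_diff=0.96, sd_diff=0.08, floor=0.7, seed=11)


def genotype_frame(array, sample_ids=None, locus_ids=None) -> pd.DataFrame:
    """Helper: build a genotype DataFrame from a plain nested list/array."""
    arr = np.asarray(array, dtype=float)
    n, m = arr.shape
    df = pd.DataFrame(
        arr,
        index=sample_ids or [f"S{i + 1:03d}" for i in range(n)],
        columns=locus_ids or [f"locus{j + 1:03d}" for j in range(m)],
    )
    df.index.name = "sample_id"
    return df
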