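import numpy as np
import pandas as pd
import pytest

from rohscape import (DepthModel, ScaffoldDef, SimulatedGenomeSpec,
                      simulate_diploid_genome)


@pytest.fixture(scope="session")
def small_genome():
    """A 10-Mb two-scaffold genome with planted ROH and per-site depth."""
    spec = SimulatedGenomeSpec(
        scaffolds=(ScaffoldDef("s1", 5_000_000), ScaffoldDef("s2", 5_000_000)),
        theta=200.0, target_f=0.3, depth=DepthModel(30.0, resolution=1),
        seed=11)
    return simulate_diploid_genome(spec), spec


@pytest.fixture(scope="session")
def flat_genome():
    """A 6-Mb genome without ROH, for rate and filter tests."""
    spec = SimulatedGenomeSpec(
        scaffolds=(ScaffoldDef("c1", 6_000_000),),
        theta=500.0, target_f=0.0, depth=DepthModel(30.0, resolution=1),
        seed=7)
    return simulate_diploid_genome(spec), spec


def brute_force_window_counts(het: pd.DataFrame, scaffold_lengths: dict,
                              window_size: int) -> pd.DataFrame:
    """Independent per-window recount: loop over windows, count sites."""
    rows = []
    for scaf, length in scaffold_lengths.items():
        pos = het.loc[het["scaffold"] == scaf, "pos"].to_numpy()
        for start in range(0, (length // window_size) * window_size,
                           window_size):
            n = int(((pos >= start) & (pos < start + window_size)).sum())
            rows.append((scaf, start, start + window_size, n))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end",
                                       "het_count"])
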