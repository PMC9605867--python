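import numpy as np
import pandas as pd
import pytest

from satmap.simulate import SignalMapParams, gen_signal_map


def make_signals(chrom_pos):
    """Minimal signal table from (chrom, pos) tuples."""
    chroms, positions = zip(*chrom_pos)
    return pd.DataFrame({"chrom": list(chroms), "pos": list(positions)})


@pytest.fixture(scope="session")
def small_genome():
    """A modest clustered signal map shared across tests."""
    params = SignalMapParams(
        n_signals=1200,
        n_hotspots=180,
        hotspot_fraction=0.6,
        n_genes=2500,
        candidate_fraction=0.04,
        gamma=3.0,
        seed=42,
    )
    signals, genes = gen_signal_map(params)
    return params, signals, genes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
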