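"""Shared fixtures: small truth-known synthetic datasets, built once per session."""

import numpy as np
import pandas as pd
import pytest

from hostscan.containers import MarkerMatrix
from hostscan.synthetic_data import SimConfig, simulate_dominant_markers, \
    simulate_sequences


@pytest.fixture(scope="session")
def two_group_fixture():
    """2 x 90 individuals, 250 neutral loci at F = 0.12, no genotyping noise."""
    cfg = SimConfig(seed=11, n_locations=1, n_per_group_per_location=90,
                    n_neutral_loci=250, n_outlier_loci=0, miscall_rate=0.0,
                    background_fst=0.12, location_fst=0.0)
    return (cfg, *simulate_dominant_markers(cfg))


@pytest.fixture(scope="session")
def outlier_fixture():
    """Planted outliers at F = 0.49 over a 0.057 background."""
    cfg = SimConfig(seed=6, n_locations=1, n_per_group_per_location=90,
                    n_neutral_loci=250, n_outlier_loci=15, miscall_rate=0.0,
                    background_fst=0.057, outlier_fst=0.49, location_fst=0.0)
    return (cfg, *simulate_dominant_markers(cfg))


@pytest.fixture(scope="session")
def seq_fixture():
    """Default-condition diploid sequence fixture (3 locations x 2 x 30)."""
    cfg = SimConfig(seed=2)
    return (cfg, *simulate_sequences(cfg))


def toy_matrix(calls, hosts=None, locations=None, sizes=None, primers=None,
               replicate_of=None, sexes=None):
    """Build a small MarkerMatrix from a 2-D 0/1 array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    ids = [f"s{i:02d}" for i in range(n)]
    hosts = hosts or ["glabra"] * (n // 2) + ["coriacea"] * (n - n // 2)
    locations = locations or ["NC"] * n
    sizes = sizes if sizes is not None else [100 + 10 * j for j in range(L)]
    primers = primers or ["P1"] * L
    loci = [f"L{sizes[j]}_{j:03d}" for j in range(L)]
    meta = pd.DataFrame({
        "host": hosts, "location": locations,
        "sex": sexes or ["F", "M"] * (n // 2) + ["F"] * (n % 2),
        "year": [2006] * n,
        "replicate_of": replicate_of or [""] * n,
    }, index=pd.Index(ids, name="sample_id"))
    info = pd.DataFrame({"size_bp": sizes, "primer": primers},
                        index=pd.Index(loci, name="locus"))
    return MarkerMatrix(pd.DataFrame(calls, index=meta.index, columns=loci),
                        meta, info)
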