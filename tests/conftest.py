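import numpy as np
import pandas as pd
import pytest

from cghsig.grid import ProbeGrid


def make_grid(chrom_sizes: dict[str, int], spacing: int = 100,
              probe_len: int = 60) -> ProbeGrid:
    """Regular probe grid for tests: one probe every ``spacing`` bp."""
    rows = []
    k = 0
    for chrom, size in chrom_sizes.items():
        for s in range(0, size - probe_len, spacing):
            rows.append((chrom, s, s + probe_len, f"P{k:05d}", None))
            k += 1
    return ProbeGrid(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "probe_id", "gene"]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture
def two_chrom_grid() -> ProbeGrid:
    # 20 probes on chr1, 10 on chr2
    return make_grid({"chr1": 2060, "chr2": 1060})
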