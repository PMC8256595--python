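import numpy as np
import pandas as pd
import pytest

from sunlipid.synthetic import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_geno():
    """A small structured genotype matrix shared by read-only tests."""
    cfg = SimConfig(
        n_lines=60, n_snps=80, n_chroms=3, subpop_count=2, fst=0.2,
        missing_rate=0.08, seed=42,
    )
    return simulate_genotypes(cfg)


@pytest.fixture()
def toy_peaks():
    """Four hand-made peaks with two samples and blank intensities."""
    return pd.DataFrame(
        {
            "peak_id": ["a", "b", "c", "d"],
            "mz": [281.24860, 902.81711, 500.0, 650.0],
            "rt": [100.0, 400.0, 200.0, 300.0],
            "mode": ["negative", "positive", "positive", "positive"],
            "blank": [1.9, 2.0, 0.0, 10.0],
            "s1": [3.0, 4.0, 1.0, 5.0],
            "s2": [5.0, 4.0, 1.0, 5.0],
        }
    )


def block_layout():
    """SNP coordinates with two tight clusters separated by wide gaps.

    Returns positions and the (start, end) member-index ranges of the two
    planted haplotype blocks.
    """
    pos = []
    cur = 1_000_000
    for _ in range(4):
        pos.append(cur)
        cur += 10_000_000
    b1 = list(range(cur, cur + 80, 10))
    pos += b1
    cur += 10_000_000
    b2 = list(range(cur, cur + 80, 10))
    pos += b2
    cur += 10_000_000
    for _ in range(4):
        pos.append(cur)
        cur += 10_000_000
    return np.array(pos, dtype=np.int64), (4, 11), (12, 19)
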