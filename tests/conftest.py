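import numpy as np
import pandas as pd
import pytest

from segscan import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_marker_map():
    """Two markers 100 cM apart (one Morgan) on a single chromosome."""
    return simulate.MarkerMap(
        ids=np.array(["m1", "m2"]),
        chromosome=np.array(["chrI", "chrI"]),
        position_bp=np.array([1, 1 + 285_714], dtype=np.int64),
        allele_A=np.array(["A", "C"]),
        allele_B=np.array(["G", "T"]),
        genetic_rate=0.35,
    )


@pytest.fixture(scope="session")
def small_map():
    """320 markers over the 16 chromosomes: fast but structurally faithful."""
    return simulate.MarkerMap.default_map(n_markers=320)


@pytest.fixture(scope="session")
def default_map():
    return simulate.MarkerMap.default_map()


def make_signal_table(per_sample_d: dict, chrom="chrI", positions=None, n_blocks=2,
                      noise_sd=0.0, rng=None) -> pd.DataFrame:
    """Build an allelic-difference table from per-sample expected d vectors."""
    n = len(next(iter(per_sample_d.values())))
    if positions is None:
        positions = np.arange(1, n + 1) * 1000
    frames = []
    for sample, d0 in per_sample_d.items():
        d0 = np.asarray(d0, float)
        for block in range(1, n_blocks + 1):
            d = d0 + (rng.normal(0, noise_sd, n) if noise_sd > 0 else 0.0)
            frames.append(
                pd.DataFrame(
                    {
                        "probe": [f"p{i:04d}" for i in range(n)],
                        "chrom": chrom,
                        "pos": positions,
                        "sample": sample,
                        "block": block,
                        "d": d,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
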