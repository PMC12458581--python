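import numpy as np
import pytest

from liveraging.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact study: 400 genes, 3 toxicant arms, 5 replicates per group."""
    return SimulationConfig(
        n_genes=400,
        n_exposure_genes=80,
        exposures=("vehicle", "TBT", "BPA.hi", "TCDD"),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                     max_start: int = 10_000, max_len: int = 300):
    """Random valid intervals for merge/round-trip properties."""
    from liveraging.io_formats import GenomicInterval

    out = []
    for i in range(n):
        start = int(rng.integers(0, max_start))
        length = int(rng.integers(1, max_len))
        out.append(
            GenomicInterval(
                str(rng.choice(chroms)), start, start + length,
                strand=str(rng.choice(["+", "-", "."])),
                name=f"iv{i}", score=float(rng.integers(0, 100)),
            )
        )
    return out
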