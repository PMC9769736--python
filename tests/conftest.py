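import numpy as np
import pandas as pd
import pytest

from magcat import RunConfig, SimulationConfig


@pytest.fixture
def run_config(tmp_path):
    return RunConfig(outdir=tmp_path / "run")


@pytest.fixture
def small_sim():
    """Small, fast simulation: 4 species x 3 copies of 5 kb genomes."""
    return SimulationConfig(seed=11, n_species=4, copies_per_species=3,
                            genome_length=5_000, n_samples=12, n_groups=3,
                            n_modules=6, kos_per_module=4,
                            n_differential_modules=2)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_bins(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Synthetic bin table spanning all three retention thresholds."""
    comp = rng.uniform(50, 100, n)
    cont = rng.uniform(0, 10, n)
    return pd.DataFrame({
        "bin_id": [f"b{i:04d}" for i in range(n)],
        "sample_id": [f"s{i % 7}" for i in range(n)],
        "length": rng.integers(5 * 10**5, 5 * 10**6, n),
        "n_contigs": rng.integers(10, 500, n),
        "n50": rng.integers(5_000, 100_000, n),
        "completeness": np.round(comp, 2),
        "contamination": np.round(cont, 2),
        "mean_depth": np.round(rng.uniform(5, 200, n), 2),
        "gc": np.round(rng.uniform(0.3, 0.7, n), 4),
        "taxonomy": [f"d__Bacteria;p__P{i % 3};s__sp{i % 11:03d}" for i in range(n)],
    })
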