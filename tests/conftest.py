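"""Shared fixtures: small simulated experiments generated at test time."""

import pandas as pd
import pytest

from barseqfit import SimulationConfig, simulate_experiment
from barseqfit import io as bio


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=120, reads_per_sample=20_000)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """pool, truth, counts, sheet for a 120-gene experiment (seed 42)."""
    return simulate_experiment(small_config, seed=42)


@pytest.fixture(scope="session")
def small_run_dir(tmp_path_factory, small_experiment):
    """The small experiment written to disk in pipeline input layout."""
    pool, truth, counts, sheet = small_experiment
    d = tmp_path_factory.mktemp("small_run")
    bio.write_pool(pool, d / "pool.tsv")
    bio.write_truth(truth, d / "truth.tsv")
    bio.write_counts(counts, d / "counts.tsv")
    bio.write_sheet(sheet, d / "sheet.tsv")
    return d


@pytest.fixture()
def tiny_pool():
    """Three-strain pool: two central insertions in one gene, one intergenic."""
    return pd.DataFrame(
        {
            "barcode": ["A" * 20, "C" * 20, "G" * 20],
            "scaffold": ["chr1"] * 3,
            "strand": ["+", "-", "+"],
            "position": [100, 200, 300],
            "locus": ["gA", "gA", "intergenic"],
            "orf_fraction": [0.3, 0.7, None],
        }
    )
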