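import pandas as pd
import pytest

from triadbias import SimulationConfig, simulate_dataset


def write_tsv(path, rows, columns):
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def triad_file(tmp_path):
    return write_tsv(
        tmp_path / "triads.tsv",
        [
            ("t1", "g1A", "g1B", "g1D", 1),
            ("t2", "g2A", "g2B", "g2D", 1),
            ("t3", "g3A", "g3B", "g3D", 0),
        ],
        ["triad_id", "gene_a", "gene_b", "gene_d", "syntenic"],
    )


@pytest.fixture
def sample_sheet_file(tmp_path):
    rows = [
        (f"leaf_{cond}_rep{r}", "leaf", cond, r)
        for cond in ("control", "stress")
        for r in (1, 2, 3)
    ]
    return write_tsv(
        tmp_path / "samples.tsv", rows, ["sample_id", "tissue", "condition", "replicate"]
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Moderate synthetic dataset at generator defaults (shared across tests)."""
    return simulate_dataset(SimulationConfig(seed=20260926, n_triads=400))


@pytest.fixture(scope="session")
def clean_dataset():
    """Low-noise dataset: tight compositions, no condition effects."""
    return simulate_dataset(
        SimulationConfig(
            seed=11,
            n_triads=400,
            dirichlet_concentration=500.0,
            shared_effect_sd=0.0,
            homeolog_effect_prob=0.0,
        )
    )
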