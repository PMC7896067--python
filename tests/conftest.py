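import numpy as np
import pandas as pd
import pytest

from sbayess.simulate import architecture_dataset, block_ld_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ma(tmp_path):
    """3-row COJO-style summary file."""
    path = tmp_path / "toy.ma"
    path.write_text(
        "SNP A1 A2 freq b se p N\n"
        "rs1 A G 0.5 0.10 0.02 1e-5 1000\n"
        "rs2 C T 0.1 -0.05 0.03 0.2 1000\n"
        "rs3 G A 0.3 0.00 0.025 0.99 900\n"
    )
    return path


@pytest.fixture
def block_ld():
    rng = np.random.default_rng(77)
    return block_ld_matrix(m=300, block_size=20, rho=0.9, nref=50_000, rng=rng)


@pytest.fixture
def recovery_data(block_ld):
    """Summary statistics generated from the point-normal MAF-coupled prior."""
    rng = np.random.default_rng(99)
    ds, beta_std = architecture_dataset(
        block_ld, h2=0.3, pi=0.05, S=-0.6, N=50_000, rng=rng)
    return ds, beta_std


@pytest.fixture
def ref_map():
    return pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3", "rs4"],
        "A1": ["A", "T", "G", "C"],
        "A2": ["G", "C", "A", "A"],
        "chrom": ["1", "1", "6", "6"],
        "pos": [1000, 2000, 30_000_000, 50_000_000],
        "freq": [0.5, 0.88, 0.31, 0.2],
    })
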