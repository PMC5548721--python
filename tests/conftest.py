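from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from phylotrx.datamodel import ORGANS, STRANDS, ExpressionTensor
from phylotrx.simulate import default_scenario, simulate

TINY_DIR = Path(__file__).parent / "data" / "tiny"


@pytest.fixture(scope="session")
def tiny_dir() -> Path:
    return TINY_DIR


@pytest.fixture(scope="session")
def sim_data():
    """One default-scenario draw shared across read-only tests."""
    return simulate(default_scenario(), seed=11)


def make_tensor(slices: dict[tuple[str, str], pd.DataFrame]) -> ExpressionTensor:
    """Tensor from partial slice frames (missing slices are all-zero)."""
    return ExpressionTensor.from_frames(slices)


def tensor_from_array(arr: np.ndarray, genes, accessions) -> ExpressionTensor:
    """Tensor directly from a (gene, accession, organ, strand) array."""
    return ExpressionTensor(
        xr.DataArray(
            arr,
            dims=("gene", "accession", "organ", "strand"),
            coords={
                "gene": list(genes),
                "accession": list(accessions),
                "organ": list(ORGANS),
                "strand": list(STRANDS),
            },
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
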