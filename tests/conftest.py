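from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cnspanel import (
    ExpressionMatrix,
    SyntheticConfig,
    make_metadata,
    make_signatures,
    simulate_cohort,
)

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


@pytest.fixture(scope="session")
def published_ratios_path() -> Path:
    return DATA_DIR / "published_marker_ratios.tsv"


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_cfg():
    """Tiny 3-cell-type mixture configuration for fast unit tests."""
    return SyntheticConfig(
        n_genes=120,
        cell_types=("neuron", "microglia", "astrocyte"),
        markers_per_type=20,
        enrichment_factor=8.0,
        baseline_proportions={"neuron": 0.6, "microglia": 0.15, "astrocyte": 0.25},
        disease_effects={"microglia": 1.0},
        n_disease=5,
        n_control=5,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture
def small_cohort(small_cfg):
    """(matrix, annotation, metadata, ledger, panels) from the tiny config."""
    signatures, panels = make_signatures(small_cfg)
    matrix, annotation, meta, ledger = simulate_cohort(
        small_cfg, signatures, seed=11, cohort="SYN"
    )
    return matrix, annotation, meta, ledger, panels


@pytest.fixture
def random_matrix(rng):
    """20x5 strictly positive continuous matrix (no ties)."""
    values = np.exp2(rng.normal(6, 1, size=(20, 5)))
    return ExpressionMatrix(
        pd.DataFrame(values,
                     index=[f"p{i}" for i in range(20)],
                     columns=[f"s{j}" for j in range(5)]),
        row_kind="probe",
    )


@pytest.fixture
def two_group_meta():
    return make_metadata({
        "sample_id": [f"s{j}" for j in range(5)],
        "group": ["disease", "disease", "control", "control", "control"],
        "age": [71, 75, 70, 80, 99],
        "sex": ["M", "F", "F", "M", "F"],
        "cohort": "X",
    })
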