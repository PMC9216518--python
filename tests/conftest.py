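import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import oncomet as om

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def small_matrix() -> om.AbundanceMatrix:
    """4 features × 6 samples, complete and positive, one run-day block."""
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.lognormal(mean=3.0, sigma=0.5, size=(4, 6)),
        index=[f"M{i}" for i in range(1, 5)],
        columns=[f"S{i}" for i in range(1, 7)],
    )
    return om.AbundanceMatrix(data, scale_tag="raw")


@pytest.fixture
def annotation_two_blocks() -> om.SampleAnnotation:
    table = pd.DataFrame(
        {
            "group": ["tumor", "tumor", "tumor", "normal", "normal", "normal"],
            "histology": ["HWIDE", "HMIN", "HMIN", "normal", "normal", "normal"],
            "recurrence": [True, False, False, False, False, False],
            "block": [0, 0, 1, 0, 1, 1],
            "freeze_time": [2.0, 10.0, 4.0, 30.0, 12.0, 24.0],
        },
        index=pd.Index([f"S{i}" for i in range(1, 7)], name="sample_id"),
    )
    return om.SampleAnnotation(table)


@pytest.fixture
def toy_signatures() -> om.PathwayCollection:
    return om.PathwayCollection(
        {
            "SIG_A": ("G00001", "G00002", "G00003", "G00004", "G00005"),
            "SIG_B": ("G00006", "G00007", "G00008", "G00009", "G00010"),
        }
    )


@pytest.fixture
def null_config() -> om.SimulationConfig:
    """No effects, no censoring, no clusters, one block, unit dilution."""
    return om.SimulationConfig(
        n_tumor=8,
        n_normal=8,
        n_metabolites=50,
        n_genes=100,
        n_blocks=1,
        censor_quantile=0.0,
        dilution_range=(1.0, 1.0),
        n_freeze_assoc=0,
        n_latent_clusters=0,
        cluster_sep=0.0,
        seed=123,
    )
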