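import numpy as np
import pandas as pd
import pytest

from ssprofit import SimConfig, simulate_dataset
from ssprofit.containers import PedigreeTable
from ssprofit.experiments import lr_calibration_replicate, multitrait_gain_replicate


@pytest.fixture(scope="session")
def small_dataset():
    """~470-animal single-trait dataset shared across fast tests."""
    cfg = SimConfig(n_founders=120, n_generations=3, n_snps=400, seed=11,
                    trait_names=("PFT",), G0=np.array([[30.0]]),
                    R0=np.array([[70.0]]), genotyped_fraction=0.5)
    return simulate_dataset(cfg, with_feedlot=True)


@pytest.fixture(scope="session")
def multi_trait_dataset():
    """Six-trait dataset at default covariances, modest size."""
    cfg = SimConfig(n_founders=80, n_generations=2, n_snps=300, seed=7,
                    genotyped_fraction=0.6)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def lr_reps():
    """Ten whole/partial LR replicates, ~2,000 animals each, h2 = 0.3."""
    return [lr_calibration_replicate(seed) for seed in range(1, 11)]


@pytest.fixture(scope="session")
def mt_reps():
    """Ten single- vs multi-trait replicates on a sparse target trait."""
    return [multitrait_gain_replicate(seed) for seed in range(1, 11)]


@pytest.fixture
def toy_pedigree():
    """Five animals: two founders, two full sibs, one full-sib offspring."""
    return PedigreeTable(pd.DataFrame({
        "id": [1, 2, 3, 4, 5],
        "sire": [0, 0, 1, 1, 3],
        "dam": [0, 0, 2, 2, 4],
    }))
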