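import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from episig.core import AnalysisConfig, BetaMatrix, SampleSheet
from episig.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down default cohort shared by unit tests (read-only)."""
    cfg = SimulationConfig(
        n_probes=3000,
        n_signature=150,
        n_confounded_per_factor=250,
        n_batch_probes=250,
        n_volume_coupled=20,
        seed=11,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def acfg():
    return AnalysisConfig(rng_seed=0)


@pytest.fixture()
def tiny_bm():
    """3 probes x 4 samples with hand-set values."""
    probes = pd.Index(["p1", "p2", "p3"], name="probe_id")
    samples = pd.Index(["s1", "s2", "s3", "s4"], name="sample_id")
    beta = pd.DataFrame(
        [[0.1, 0.2, 0.8, 0.9], [0.5, 0.5, 0.5, 0.5], [0.0, 1.0, 0.3, 0.7]],
        index=probes, columns=samples,
    )
    detp = pd.DataFrame(0.001, index=probes, columns=samples)
    beads = pd.DataFrame(10.0, index=probes, columns=samples)
    return BetaMatrix(beta, detp, beads)


@pytest.fixture()
def tiny_sheet():
    return SampleSheet(
        pd.DataFrame(
            {
                "genotype": ["WT", "WT", "KS1", "KS1"],
                "treatment": ["vehicle"] * 4,
                "day_of_sacrifice": [1, 2, 1, 2],
            },
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )
    )
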