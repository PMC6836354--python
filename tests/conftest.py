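from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cmsscan.pipeline import run_full_pipeline
from cmsscan.synthetic_data import SimConfig, simulate_trio

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    # fresh, fixed-seed stream per test: results do not depend on which
    # other tests ran before
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_sim():
    """Scaled-down trio shared by fast unit tests."""
    return simulate_trio(SimConfig.tiny(0))


@pytest.fixture(scope="session")
def study_sim():
    """Full study-condition trio (paper-scale defaults)."""
    return simulate_trio(SimConfig(seed=1))


@pytest.fixture(scope="session")
def study_pipeline(study_sim):
    """Full pipeline run on the study-condition trio."""
    g = study_sim.genomes
    return run_full_pipeline(
        g["cms"],
        g["maintainer"],
        study_sim.annotations["cms"],
        study_sim.annotations["maintainer"],
        g["donor"],
    )


def random_dna(rng, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
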