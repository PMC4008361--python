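import numpy as np
import pytest
from hypothesis import settings

from annotforge.pipeline import run_simulated_pipeline
from annotforge.synthetic import SimulationConfig, simulate_all

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One full simulated dataset under the default study conditions."""
    cfg = SimulationConfig(seed=1)
    genome, truth, tracks, fragments, peptides, domains, reactions, orthologs = (
        simulate_all(cfg)
    )
    return {
        "config": cfg, "genome": genome, "truth": truth, "tracks": tracks,
        "fragments": fragments, "peptides": peptides, "domains": domains,
        "reactions": reactions, "orthologs": orthologs,
    }


@pytest.fixture(scope="session")
def default_pipeline():
    """The end-to-end pipeline result on the default dataset."""
    return run_simulated_pipeline(SimulationConfig(seed=1))


def jaccard(a, b) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0
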