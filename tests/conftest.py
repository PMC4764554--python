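import numpy as np
import pytest

from nmdshield.simulate import (
    SimulationConfig,
    simulate_annotation_and_sequences,
    simulate_clip_peaks,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A reduced synthetic study used by fast structural tests."""
    return SimulationConfig(seed=7, n_genes=300)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    ann, genome, truth = simulate_annotation_and_sequences(small_cfg)
    counts = simulate_counts(small_cfg, truth)
    peaks = simulate_clip_peaks(small_cfg, truth, ann)
    return {
        "cfg": small_cfg,
        "ann": ann,
        "genome": genome,
        "truth": truth,
        "counts": counts,
        "peaks": peaks,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160108)
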