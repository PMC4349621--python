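import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mirhd import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20150301)


@pytest.fixture(scope="session")
def rich_annotation():
    """Genome + annotation with multi-locus matures, overlapping pairs and
    both strands — the structures the counting rules must disambiguate."""
    cfg = sd.SimulationConfig(seed=42, n_mirnas=40, n_multilocus=4,
                              n_overlap_pairs=3)
    genome, matures = sd.simulate_annotation(cfg)
    return cfg, genome, matures


@pytest.fixture(scope="session")
def small_cohort():
    """A small full cohort: samples, counts and planted truth."""
    cfg = sd.SimulationConfig(
        seed=7, n_mirnas=60, n_multilocus=2, n_overlap_pairs=1,
        n_hd=10, n_grade0=2, n_control=10, n_de=10,
        base_log2_mean_range=(2.0, 7.0),
    )
    samples, counts, truth = sd.simulate_cohort(cfg)
    return cfg, samples, counts, truth
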