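import numpy as np
import pandas as pd
import pytest

from bioidkit import SpectralCountExperiment


def make_experiment(counts: dict, manifest: list) -> SpectralCountExperiment:
    """counts: {run_id: {prey: count}}; manifest: [(run, bait, role, condition)]."""
    man = pd.DataFrame(
        manifest, columns=["run_id", "bait_id", "role", "condition"]
    ).set_index("run_id")
    wide = pd.DataFrame(counts).T.fillna(0).astype(int)
    wide = wide.reindex(index=man.index, fill_value=0).sort_index(axis=1)
    return SpectralCountExperiment(counts=wide, manifest=man)


@pytest.fixture
def tiny_experiment():
    """Two baits x two replicates plus three controls over four preys."""
    manifest = [
        ("c1", "ctrl", "control", "cycling"),
        ("c2", "ctrl", "control", "cycling"),
        ("c3", "ctrl", "control", "ciliated"),
        ("b1r1", "PC1", "test", "cycling"),
        ("b1r2", "PC1", "test", "cycling"),
        ("b2r1", "PC2", "test", "cycling"),
        ("b2r2", "PC2", "test", "cycling"),
    ]
    counts = {
        "c1": {"A": 1, "B": 0, "C": 2, "D": 0},
        "c2": {"A": 0, "B": 1, "C": 3, "D": 0},
        "c3": {"A": 2, "B": 0, "C": 1, "D": 0},
        "b1r1": {"A": 20, "B": 0, "C": 2, "D": 15},
        "b1r2": {"A": 18, "B": 1, "C": 3, "D": 12},
        "b2r1": {"A": 0, "B": 22, "C": 1, "D": 0},
        "b2r2": {"A": 1, "B": 19, "C": 2, "D": 1},
    }
    return make_experiment(counts, manifest)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
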