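import numpy as np
import pandas as pd
import pytest

import tfhscreen as tfs


@pytest.fixture(scope="session")
def small_library():
    """20 genes x 4 guides + 12 controls."""
    genes = [f"Gene{i:02d}" for i in range(1, 21)]
    return tfs.build_library(genes, guides_per_gene=4, n_controls=12, seed=7)


@pytest.fixture(scope="session")
def pid_like_library():
    """80 genes x 5 guides + 20 controls, the proof-of-concept design."""
    genes = [f"Pid{i:02d}" for i in range(1, 81)]
    return tfs.build_library(genes, guides_per_gene=5, n_controls=20, seed=11)


@pytest.fixture(scope="session")
def neutral_screen(pid_like_library):
    """One all-neutral-truth simulated screen at design defaults."""
    truth = tfs.ScreenTruth.neutral(pid_like_library)
    cfg = tfs.ScreenConfig(seed=101)
    table = tfs.simulate_screen(pid_like_library, truth, cfg)
    return table, truth, cfg
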