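import numpy as np
import pytest
from hypothesis import settings

from ermetrics.grid_metrics import ETDRSGrid
from ermetrics.synthetic_fundus import generate_vessel_tree, ground_truth_metrics, render_fundus
from ermetrics.vessel_extraction import extract_graph

settings.register_profile("repro", derandomize=True, deadline=None, max_examples=40)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def grid():
    return ETDRSGrid()


@pytest.fixture(scope="session")
def tree():
    """One deterministic vessel tree shared across tests."""
    return generate_vessel_tree(arcades=8, branch_depth=3, seed=1)


@pytest.fixture(scope="session")
def tree_truth(tree, grid):
    return ground_truth_metrics(tree, grid)


@pytest.fixture(scope="session")
def rendered(tree):
    """Noiseless infrared-style render of the shared tree."""
    return render_fundus(tree, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def extracted(rendered):
    """Vessel graph extracted from the shared render (expensive; reused)."""
    return extract_graph(rendered)
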