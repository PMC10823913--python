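import numpy as np
import pytest

from virtualforest.core import FieldPlot, StandSummary, TreeRecord
from virtualforest.synthetic import SyntheticConfig, simulate_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def broadleaf_map():
    return {
        "Fa.sy.": True,
        "Qu.pe.": True,
        "Ac.ps.": True,
        "Pi.ab.": False,
        "Ab.al.": False,
    }


@pytest.fixture
def two_tree_plot():
    """Two conifers, dbh 20 and 30 cm, equal weights: Dg = sqrt(650)."""
    return FieldPlot(
        plot_id="p1",
        trees=[
            TreeRecord("Pi.ab.", 20.0, 25.0, broadleaf=False),
            TreeRecord("Pi.ab.", 30.0, 25.0, broadleaf=False),
        ],
    )


@pytest.fixture
def mixed_plot():
    """Two species, both classes represented."""
    return FieldPlot(
        plot_id="pm",
        trees=[
            TreeRecord("Fa.sy.", 25.0, 100.0, broadleaf=True),
            TreeRecord("Fa.sy.", 35.0, 50.0, broadleaf=True),
            TreeRecord("Pi.ab.", 30.0, 80.0, broadleaf=False),
            TreeRecord("Ab.al.", 40.0, 20.0, broadleaf=False),
        ],
    )


@pytest.fixture(scope="session")
def small_landscape():
    """A 12x12 landscape with 50 plots, shared across read-only tests."""
    cfg = SyntheticConfig(nx=12, ny=12, n_plots=50, seed=42)
    return simulate_landscape(cfg)


def random_plot(rng, n_trees=None, both_classes=True):
    """Arbitrary plot for brute-force property checks."""
    n = int(n_trees or rng.integers(2, 9))
    species = ["Fa.sy.", "Qu.pe.", "Pi.ab.", "Ab.al."]
    broadleaf = {"Fa.sy.": True, "Qu.pe.": True, "Pi.ab.": False, "Ab.al.": False}
    trees = []
    for i in range(n):
        if both_classes and i == 0:
            sp = "Fa.sy."
        elif both_classes and i == 1:
            sp = "Pi.ab."
        else:
            sp = species[rng.integers(len(species))]
        trees.append(
            TreeRecord(
                sp,
                float(rng.uniform(8, 60)),
                float(rng.uniform(5, 200)),
                broadleaf=broadleaf[sp],
            )
        )
    return FieldPlot(plot_id=f"r{rng.integers(1e6)}", trees=trees)


@pytest.fixture
def make_random_plot():
    return random_plot
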