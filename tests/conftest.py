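import numpy as np
import pandas as pd
import pytest

from cropdiv.io_fao import Panel
from cropdiv.phylo import DatedTree


@pytest.fixture
def fixture_tree() -> DatedTree:
    """((A,B)ab,C)root dated with root=10 My, ab=5 My."""
    return DatedTree.read_newick("((A,B)ab,C)root;").bladj_date({"root": 10, "ab": 5})


@pytest.fixture
def star_tree_factory():
    """Star tree with n tips all attached to a root of the given age."""

    def make(n: int, radius: float) -> DatedTree:
        tips = ",".join(f"t{i}" for i in range(n))
        return DatedTree.read_newick(f"({tips})root;").bladj_date({"root": radius})

    return make


@pytest.fixture
def panel_factory():
    """Build a Panel from (region, year, group, area) tuples."""

    def make(rows, coverage=None) -> Panel:
        df = pd.DataFrame(rows, columns=["region", "year", "group", "area"])
        return Panel(df, coverage=coverage)

    return make


@pytest.fixture
def toy_panel(panel_factory) -> Panel:
    return panel_factory(
        [
            ("north", 1961, "wheat", 100.0),
            ("north", 1961, "maize", 50.0),
            ("north", 2014, "wheat", 80.0),
            ("north", 2014, "maize", 60.0),
            ("north", 2014, "barley", 10.0),
            ("south", 1961, "rice", 200.0),
            ("south", 2014, "rice", 150.0),
            ("south", 2014, "cassava", 30.0),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
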