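import numpy as np
import pytest

from immunodyn.knowledge import (RelationshipType, default_ruleset,
                                 enumerate_relationships)
from immunodyn.panel import Biomarker, Panel, default_panel


@pytest.fixture(scope="session")
def panel50():
    return default_panel()


@pytest.fixture(scope="session")
def km50(panel50):
    """Full knowledge model over the default 50-biomarker panel."""
    return enumerate_relationships(panel50, default_ruleset())


@pytest.fixture
def toy_panel():
    """2 cytokines + 1 cell, the smallest panel exercising every type."""
    return Panel([Biomarker("A", "cytokine"), Biomarker("B", "cytokine"),
                  Biomarker("C", "cell")])


@pytest.fixture
def toy_type():
    return RelationshipType("T1", "cytokine", "cell", "cytokine")


@pytest.fixture
def toy_km(toy_panel, toy_type):
    """4 relationships: {A,B} modulating C -> {A,B}."""
    return enumerate_relationships(toy_panel, [toy_type])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
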