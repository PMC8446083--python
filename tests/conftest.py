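import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import poleward as pw

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def transect() -> pw.TransectData:
    """One default synthetic transect shared by read-only tests."""
    return pw.simulate_transect(pw.TransectConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_transect() -> pw.TransectData:
    return pw.simulate_transect(pw.TransectConfig(seed=5, noise_sd=0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def toy_taxonomy() -> pw.Taxonomy:
    """root -> phylum Rhizaria -> (class Filosa -> genus Cercozoa) plus
    class-less leaves Gromiidae / unclassified-Rhizaria, and a second
    complete phylum for contrast."""
    rows = [
        ("root", "root", "root", "root"),
        ("p1", "root", "phylum", "Rhizaria"),
        ("c1", "p1", "class", "Filosa"),
        ("g1", "c1", "genus", "Cercozoa"),
        ("g2", "p1", "genus", "Gromiidae"),
        ("g3", "p1", "genus", "unclassified-Rhizaria"),
        ("p2", "root", "phylum", "Ochrophyta"),
        ("c2", "p2", "class", "Bacillariophyceae"),
        ("g4", "c2", "genus", "Thalassiosira"),
    ]
    return pw.Taxonomy(pd.DataFrame(rows, columns=["node_id", "parent_id", "rank", "name"]))
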