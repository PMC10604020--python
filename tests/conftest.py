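import numpy as np
import pandas as pd
import pytest

from quinscreen.scoring import ReferenceStats, SCORED_PROPERTIES
from quinscreen.synthetic import SimulationConfig


@pytest.fixture
def small_cfg():
    """A cohort small enough for fast unit tests."""
    return SimulationConfig(seed=11, n_compounds=400, n_refs=10)


@pytest.fixture
def ref_stats():
    """Hand-specified reference statistics covering every scored property."""
    means = {
        "mw": 320.0, "logp": 3.0, "hbd": 2.0, "hba": 5.0, "tpsa": 75.0,
        "rotb": 6.0, "mr": 95.0, "heavy_atoms": 23.0,
        "ld50": 700.0, "mutagenicity": 0.4, "dev_tox": 0.3, "bf": 1.0,
        "sa": 40.0,
    }
    stds = {
        "mw": 45.0, "logp": 1.2, "hbd": 1.0, "hba": 1.5, "tpsa": 20.0,
        "rotb": 2.0, "mr": 12.0, "heavy_atoms": 4.0,
        "ld50": 350.0, "mutagenicity": 0.2, "dev_tox": 0.15, "bf": 0.8,
        "sa": 12.0,
    }
    assert set(means) == set(SCORED_PROPERTIES)
    return ReferenceStats(means=means, stds=stds, n_refs=12)


@pytest.fixture
def centroid_vector(ref_stats):
    """A compound sitting exactly at the reference centroid."""
    from quinscreen.admet import PropertyVector

    m = ref_stats.means
    return PropertyVector(
        mw=m["mw"], logp=m["logp"], hbd=int(m["hbd"]), hba=int(m["hba"]),
        tpsa=m["tpsa"], rotb=int(m["rotb"]), mr=m["mr"],
        heavy_atoms=int(m["heavy_atoms"]), carbons=18, heteroatoms=5, rings=3,
        sa=m["sa"], ld50=m["ld50"], mutagenicity=m["mutagenicity"],
        dev_tox=m["dev_tox"], bf=m["bf"],
    )
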