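import numpy as np
import pytest

from rookery.synthetic import (FixtureConfig, generate_study_like_dataset,
                               make_toy_tables)


@pytest.fixture(scope="session")
def toy():
    return make_toy_tables()


@pytest.fixture(scope="session")
def small_fixture():
    """A reduced study-shaped alignment (fast, but with all the features:
    two haplogroups, islands, beaches, one perturbed beach)."""
    cfg = FixtureConfig(
        islands={"BoaVista": 60, "Sal": 40, "Maio": 40, "SaoVicente": 30},
        hg2_mixture={"BoaVista": 0.02, "Sal": 0.02, "Maio": 0.02,
                     "SaoVicente": 0.7},
        beaches={"BoaEsperanca": 25, "Lacacao": 20, "PontaPesqueira": 15},
    )
    return generate_study_like_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def default_fixture():
    """The full default study-shaped alignment (defaults are the study
    conditions)."""
    return generate_study_like_dataset(seed=11)


@pytest.fixture()
def fasta_pair(tmp_path, small_fixture):
    """The small fixture written out as FASTA + population map."""
    from rookery.synthetic import write_fixture
    fa = tmp_path / "fix.fasta"
    pm = tmp_path / "fix.popmap.tsv"
    write_fixture(small_fixture, fa, pm)
    return fa, pm
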