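from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from asebias.sequences import Exome, Exon
from asebias.synthetic import SimulationConfig, simulate_allele_pair

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20130807)


@pytest.fixture
def small_exome():
    return Exome(
        [
            Exon("e1", "ACGTACGTAC"),
            Exon("e2", "TTTTGGGGCC"),
        ]
    )


@pytest.fixture(scope="session")
def snv_pair():
    """The standard intraspecific-style synthetic pair used across tests."""
    cfg = SimulationConfig(
        seed=11, n_exons=20, exon_length_range=(300, 600), snv_rate=0.01
    )
    return simulate_allele_pair(cfg)


def random_exome(rng, n_exons, length_range, prefix="x") -> Exome:
    exons = []
    for i in range(n_exons):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        exons.append(Exon(f"{prefix}{i}", seq))
    return Exome(exons)
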