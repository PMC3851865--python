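import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from aliquote.model import ParalogPair, Parameters
from aliquote.simulate import SimConfig, simulate


def pairs_from_frame(df):
    return [
        ParalogPair(r.gene_a, r.gene_b, r.similarity) for r in df.itertuples()
    ]


@pytest.fixture(scope="session")
def clean_sim_small():
    """Unrearranged, unfractionated hexaploid: 3 ancestral chromosomes of
    30 families, every family a full 3-clique."""
    return simulate(
        SimConfig(
            C=3,
            genes_per_chromosome=30,
            inversions=0,
            translocations=0,
            fusions=0,
            fissions=0,
            retention=(1.0, 1.0, 1.0),
            old_wgd_fraction=0.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def noisy_sim_small():
    """Small rearranged + fractionated + contaminated scenario for
    end-to-end tests."""
    return simulate(
        SimConfig(
            C=3,
            genes_per_chromosome=60,
            inversions=6,
            translocations=1,
            fusions=1,
            fissions=1,
            seed=23,
        )
    )


@pytest.fixture
def default_params():
    return Parameters(k=3, r=40.0, j=15.0, t=3)


@pytest.fixture
def study_params():
    """Parameters of the validation studies: jump penalty in the analytic
    window [r, (k-1)r) and the similarity cutoff at 72."""
    return Parameters(k=3, r=40.0, j=40.0, t=3, sim_min=72.0)
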