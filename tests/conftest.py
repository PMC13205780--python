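import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cmcpminer.synthetic_data import SimScenario, simulate_family


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def coherent_family():
    """A 12-member family at 10% divergence (no confounders)."""
    scenario = SimScenario(seed=4, family_size=12, divergence=0.10,
                           protein_length=50)
    fam, _ = simulate_family(scenario)
    return fam


@pytest.fixture(scope="session")
def coherent_hmm(coherent_family):
    from cmcpminer.msa import progressive_align
    from cmcpminer.profile_hmm import build_profile

    aln = progressive_align(coherent_family.members,
                            family=coherent_family.name)
    return build_profile(aln)
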