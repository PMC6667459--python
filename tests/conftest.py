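import numpy as np
import pytest
from hypothesis import settings

from xlopen.sequence_db import Protein

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_proteins():
    """A handful of hand-written proteins with K, C, and M residues so every
    hypothesis kind (cross/loop/mono/regular, BS3 and SS) has material."""
    return [
        Protein("P1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
        Protein("P2", "GSHMKLVINGKTLKGEITVEAVDAAEAEKIFKQY"),
        Protein("P3", "ACDEFKGHIKLMNPQRSTVWYKACDEFGHIK"),
        Protein("P4", "MMKWVTFISLLFLFSSAYSRGVFRRDAHKSEVAHR"),
    ]
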