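import numpy as np
import pytest

from torsioncouple.opening import SigmoidOpening
from torsioncouple.torsion import TorsionParameters, TranscriptionUnit
from torsioncouple.transcription import PromoterModel


@pytest.fixture
def cmv_like_opening() -> SigmoidOpening:
    """The package's default simulation promoter (synthetic CMV-like)."""
    return SigmoidOpening(sigma_c=-0.042, width=0.01, amplitude=3.0, slope=2.0, offset=2.0)


@pytest.fixture
def promoter(cmv_like_opening) -> PromoterModel:
    return PromoterModel(opening=cmv_like_opening)


@pytest.fixture
def torsion() -> TorsionParameters:
    return TorsionParameters(sigma0=0.0, decay_length=1000.0, alpha=3e-5)


@pytest.fixture
def kb_unit() -> TranscriptionUnit:
    """A 1-kb plus-strand gene at unit rate (the illustrative standard gene)."""
    return TranscriptionUnit("gene", 1000, 2000, "+", 1.0)
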