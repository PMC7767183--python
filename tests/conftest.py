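import math

import pytest

from sebupen.chem import AcidBaseConstants, AlcoholamineSpec
from sebupen.optical import PixelCalibration, TubeGeometry
from sebupen.stoichiometry import SebumComposition


@pytest.fixture
def ampd() -> AlcoholamineSpec:
    """AMPD with the pKa-derived pKb = 5.24."""
    return AlcoholamineSpec()


@pytest.fixture
def hydrolysis_constants() -> AcidBaseConstants:
    """Constants for the stearate-salt hydrolysis treatment."""
    return AcidBaseConstants(
        pKb=-math.log10(6.309e-6), pKa=-math.log10(1.778e-5)
    )


@pytest.fixture
def sebum() -> SebumComposition:
    return SebumComposition()


@pytest.fixture
def geometry() -> TubeGeometry:
    return TubeGeometry()


@pytest.fixture
def calibration() -> PixelCalibration:
    return PixelCalibration()
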