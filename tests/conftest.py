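import numpy as np
import pytest
from hypothesis import settings

import aedesdyn as ad

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

#: Fitted/literature baseline rates used throughout (diffusion and mobile
#: mortality from the dispersal fit, the rest from laboratory studies).
BASE = dict(D=18969.0, gamma=0.0625, mu1_base=0.1177, mu2=0.0250, r=34.0, e=0.24, k=0.059)

#: Street / house / area-weighted coefficient triple of the heterogeneous
#: urban scenario (houses = half the street values).
STREET = dict(D=18969.0, mu1=0.2354, mu2=0.0500)
HOUSE = dict(D=9484.5, mu1=0.1177, mu2=0.0250)
HOMOG = dict(D=12440.0, mu1=0.1544, mu2=0.0328)

#: Observed Rb-tagged egg detections per ring in the mark-release-recapture
#: experiment, and the kernel/trap values fitted to them.
OBSERVED_COUNTS = (0.0, 2.0, 12.0, 20.0, 17.0)
FITTED = dict(D=18969.0, mu=0.1177, alpha=0.0642)
RELEASE = dict(M0=3000.0, t=7.0)


@pytest.fixture
def base_params() -> ad.ParameterSet:
    return ad.ParameterSet(**BASE)


@pytest.fixture
def homog_params() -> ad.ParameterSet:
    """Homogeneous-scenario rates (area-weighted street/house averages)."""
    return ad.ParameterSet(
        D=HOMOG["D"],
        gamma=BASE["gamma"],
        mu1_base=HOMOG["mu1"],
        mu2=HOMOG["mu2"],
        r=BASE["r"],
        e=BASE["e"],
        k=BASE["k"],
    )


@pytest.fixture
def street_params() -> ad.ParameterSet:
    return ad.ParameterSet(
        D=STREET["D"],
        gamma=BASE["gamma"],
        mu1_base=STREET["mu1"],
        mu2=STREET["mu2"],
        r=BASE["r"],
        e=BASE["e"],
        k=BASE["k"],
    )


@pytest.fixture
def release() -> ad.ReleaseSpec:
    return ad.ReleaseSpec(**RELEASE)


@pytest.fixture
def annuli() -> ad.AnnulusData:
    return ad.AnnulusData(counts=OBSERVED_COUNTS)


@pytest.fixture
def block_domain():
    """Small synthetic city: 5x5 blocks of 50 m, 10 m streets, one merged
    2x2 super-block in the center, 10 m cells."""
    layout = ad.BlockLayout(
        block_size=50.0,
        street_width=10.0,
        n_blocks_x=5,
        n_blocks_y=5,
        big_block_positions=((2, 2),),
    )
    return ad.make_block_grid(layout, dx=10.0)
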