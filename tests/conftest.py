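import numpy as np
import pytest

from leafvcmax.biochem import BiochemParams
from leafvcmax.coupling import CouplingParams
from leafvcmax.leaf_rt import LeafOpticalParams
from leafvcmax.synth import (
    SyntheticTruth,
    make_lamp_spectrum,
    make_protocol,
    make_sac_fixture,
    simulate_dataset,
)

NO_NOISE = {"spectra": 0.0, "a": 0.0, "pam": 0.0}


@pytest.fixture(scope="session")
def sacs():
    return make_sac_fixture()


@pytest.fixture(scope="session")
def lamp():
    return make_lamp_spectrum()


@pytest.fixture(scope="session")
def default_optics():
    return LeafOpticalParams()


@pytest.fixture(scope="session")
def interior_optics():
    """A leaf with every static parameter strictly inside its range."""
    return LeafOpticalParams(
        cab=45.0, ccar=12.0, cant=1.0, cw=0.012, cdm=0.015,
        n_layers=1.6, cs=0.05,
    )


def make_noiseless_dataset(kind, sacs, lamp, optical=None, vcmax=85.0,
                           kn0=3.0, sigma_scale=0.01, seed=1, **biochem_kw):
    """Noiseless synthetic curve with truth away from the fit initials."""
    truth = SyntheticTruth(
        optical=optical or LeafOpticalParams(
            cab=45.0, ccar=12.0, cant=1.0, cw=0.012, cdm=0.015,
            n_layers=1.6, cs=0.05,
        ),
        biochem=BiochemParams(vcmax=vcmax, kn0=kn0, **biochem_kw),
        coupling=CouplingParams(sigma_scale=sigma_scale),
        noise=dict(NO_NOISE),
        seed=seed,
    )
    return simulate_dataset(truth, make_protocol(kind), lamp, sacs)


@pytest.fixture(scope="session")
def light_dataset(sacs, lamp):
    return make_noiseless_dataset("light", sacs, lamp)


@pytest.fixture(scope="session")
def co2_dataset(sacs, lamp):
    return make_noiseless_dataset("co2", sacs, lamp)
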