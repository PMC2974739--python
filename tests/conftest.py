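import numpy as np
import pytest

from tevcperm.biophysics import PhysicalConstants, SolutionSpec
from tevcperm.simulate import ChannelModel, OocyteModel, Protocol

ROOM = PhysicalConstants()  # T = 293.15 K


@pytest.fixture
def constants():
    return ROOM


@pytest.fixture
def car4():
    """Biionic 4 mM Ca2+ Ringer: NMDG replaces every monovalent."""
    return SolutionSpec(
        label="4CaR+Gly",
        ion_concentrations={"NMDG": 108.6, "Ca": 4.0},
        agonists={"glycine": 10.0},
    )


@pytest.fixture
def car4_blank():
    return SolutionSpec(label="4CaR", ion_concentrations={"NMDG": 108.6, "Ca": 4.0})


@pytest.fixture
def nfr():
    return SolutionSpec(
        label="NFR", ion_concentrations={"Na": 115.0, "K": 2.5, "Ca": 1.8}
    )


@pytest.fixture
def quiet_oocyte():
    """No leak, no noise, fixed mono_i matching the default calibration."""
    return OocyteModel(
        leak_conductance=0.0,
        leak_reversal=-20.0,
        internal_concentrations={"Mono": 89.38, "Ca": 0.0},
        noise_sd=0.0,
    )


@pytest.fixture
def gly_channel():
    """Fully glycine-gated channel, no block."""
    return ChannelModel(
        pca_over_pmono=2.3,
        max_conductance_scale=20.0,
        agonist_efficacy={"glycine": 1.0, "glutamate+glycine": 1.0},
    )


@pytest.fixture
def ramp_protocol():
    return Protocol(kind="ramp", sample_rate_hz=1000.0)


def make_ramp_protocol(**kw) -> Protocol:
    base = dict(kind="ramp", sample_rate_hz=1000.0)
    base.update(kw)
    return Protocol(**base)


def make_application_protocol(segments, **kw) -> Protocol:
    base = dict(
        kind="application",
        hold_mv=-70.0,
        sample_rate_hz=200.0,
        exchange_tau_s=0.3,
        application_timeline=tuple(segments),
    )
    base.update(kw)
    return Protocol(**base)
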