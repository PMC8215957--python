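import numpy as np
import pytest
from hypothesis import settings

from ubblimb import config as cfg
from ubblimb.limb_model import attach_boot, build_limb_chain

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def calibrated_chain():
    lib = cfg.calibrated_materials()
    return build_limb_chain(lib["plantar_tissue"], lib["plantar_fascia"])


@pytest.fixture(scope="session")
def booted_chain(calibrated_chain):
    return attach_boot(calibrated_chain, cfg.default_boot_config())


@pytest.fixture(scope="session")
def pendulum_chain():
    lib = cfg.calibrated_materials()
    return build_limb_chain(lib["plantar_tissue"], lib["plantar_fascia"],
                            boundary_mode="impactor")


@pytest.fixture
def half_sine():
    from ubblimb.signals import Signal
    dt = 4e-5
    t = dt * np.arange(512)
    vals = np.where(t <= 10e-3, np.sin(np.pi * t / 10e-3), 0.0)
    return Signal(0.0, dt, vals, unit="N")
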