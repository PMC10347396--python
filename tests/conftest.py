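import numpy as np
import pytest

import psmcea
from psmcea.sensitivity_analysis import EconModel
from psmcea.parametric_survival import ParametricCurve


@pytest.fixture(scope="session")
def demo_config():
    return psmcea.default_study_config()


@pytest.fixture(scope="session")
def demo_model(demo_config):
    """The shipped synthetic study, built once per session."""
    return psmcea.build_model(demo_config)


@pytest.fixture(scope="session")
def exp_model(demo_config):
    """A fast analytic model: exponential curves at the published medians
    (OS 23.4 vs 16.8 months, PFS 9.9 vs 5.1 months), demo cost inputs."""
    from psmcea.pipeline import costs_from_config
    ln2 = np.log(2.0)
    return EconModel(
        os_tdxd=ParametricCurve("exponential", (ln2 / 23.4,)),
        pfs_tdxd=ParametricCurve("exponential", (ln2 / 9.9,)),
        os_chemo=ParametricCurve("exponential", (ln2 / 16.8,)),
        pfs_chemo=ParametricCurve("exponential", (ln2 / 5.1,)),
        costs=costs_from_config(demo_config),
    )


@pytest.fixture(scope="session")
def weibull_ipd():
    """Uncensored Weibull(1.4, 20) sample used by several fitting tests."""
    spec = psmcea.ArmSpec("w", "weibull", (1.4, 20.0), 5000)
    return psmcea.simulate_arm(spec, 42)
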