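import pytest

from fatiguesim import MaterialParams, build_bar_mesh, hourglass_profile
from fatiguesim.sn import TI64_REFERENCE_LIFETIMES, calibrate_damage_parameters


@pytest.fixture(scope="session")
def ti64_params() -> MaterialParams:
    """Reference Ti-6Al-4V parameter set (literal defaults)."""
    return MaterialParams()


@pytest.fixture(scope="session")
def default_mesh():
    """64-element mesh of the default cylindrical-gauge coupon."""
    return build_bar_mesh(hourglass_profile(), 64)


@pytest.fixture(scope="session")
def anchor_calibration(default_mesh):
    """Damage parameters calibrated to the reference lifetimes at 350/600 MPa.

    Session-scoped: the calibration is deterministic and takes a few seconds,
    and several acceptance checks reuse it.
    """
    anchors = [(350.0, TI64_REFERENCE_LIFETIMES[350.0]), (600.0, TI64_REFERENCE_LIFETIMES[600.0])]
    return calibrate_damage_parameters(anchors, engine="specimen", mesh=default_mesh)
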