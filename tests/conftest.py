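import numpy as np
import pytest

from coflow import (
    ChannelGeometry,
    CircuitParameters,
    CorrectionFactorModel,
    FluidPair,
    builtin_cf_model,
)


@pytest.fixture(scope="session")
def geom_h20() -> ChannelGeometry:
    """Stock geometry with the 20 µm channel depth."""
    return ChannelGeometry(l1=7500.0, l2=4800.0, w=250.0, h=20.0)


@pytest.fixture(scope="session")
def cf20() -> CorrectionFactorModel:
    """Shipped quintic correction-factor model for h = 20 µm."""
    return builtin_cf_model(20.0)


@pytest.fixture(scope="session")
def cf_const() -> CorrectionFactorModel:
    """Constant correction factor at the h = 20 µm CF₀."""
    return CorrectionFactorModel.constant(1.183)


@pytest.fixture(scope="session")
def demo_params(geom_h20) -> CircuitParameters:
    """Circuit parameters of the worked demonstration (h = 20 µm)."""
    return CircuitParameters(
        geometry=geom_h20,
        fluids=FluidPair(mu_r=1.0, mu_b=2.2266),
        C1=53.3,
        C2=1398.2,
        CF0=1.183,
    )


def random_circuit(
    rng: np.random.Generator,
    geom: ChannelGeometry,
    identifiable_only: bool = True,
):
    """Random physically plausible parameter set (C1 < C2 guaranteed).

    With ``identifiable_only`` the draw is restricted to C2 > k²·C1
    (k = 1 + (l1/l2)·CF0), the regime where the eigenvalue inversion has a
    unique ordered root; measured compliance ratios sit well inside it.
    """
    cf0 = 1.183
    k = 1.0 + (geom.l1 / geom.l2) * cf0
    while True:
        c1 = float(np.exp(rng.uniform(np.log(10.0), np.log(200.0))))
        c2 = float(np.exp(rng.uniform(np.log(500.0), np.log(5000.0))))
        if not identifiable_only or c2 > k * k * c1:
            break
    mu_b = float(rng.uniform(1.0, 4.0))
    return CircuitParameters(
        geometry=geom,
        fluids=FluidPair(mu_r=1.0, mu_b=mu_b),
        C1=c1,
        C2=c2,
        CF0=cf0,
    )
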