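import pytest

from selfbuckle import build_section

#: Hardwood constants used for all dimensional examples.
E_WOOD = 1.1e10  # N/m^2
RHO_WOOD = 526.0  # kg/m^3
G = 9.81  # m/s^2
R_TRUNK = 0.23  # m

#: (4C)^(1/3) with Greenhill's C = 1.959; normalises xi_c into f.
GREENHILL_NORM = (4.0 * 1.959) ** (1.0 / 3.0)


@pytest.fixture(scope="session")
def wood_section():
    return build_section(E=E_WOOD, rho0=RHO_WOOD, g=G, r=R_TRUNK)
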