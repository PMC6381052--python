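import numpy as np
import pytest

from isoyield.isotope import ChemTimePoint, IncubationReplicate, IsotopeTimePoint


def make_replicate(
    a_series,
    times=None,
    nh4=None,
    vss0=1.0,
    substrate="ammonium",
    a_medium=0.99,
    temperature=28.0,
):
    """Hand-build a replicate from an atom-fraction series."""
    n = len(a_series)
    if times is None:
        times = list(range(n))
    if nh4 is None:
        nh4 = np.linspace(50.0, 0.0, n)
    iso = [IsotopeTimePoint(t, a) for t, a in zip(times, a_series)]
    chem = [
        ChemTimePoint(t, nh4_n=c if substrate == "ammonium" else 0.0,
                      no2_n=c if substrate == "nitrite" else 0.0)
        for t, c in zip(times, nh4)
    ]
    return IncubationReplicate(
        isotope_series=iso,
        chem_series=chem,
        vss0=vss0,
        substrate=substrate,
        temperature=temperature,
        a13C_medium=a_medium,
    )


@pytest.fixture
def simple_replicate():
    return make_replicate([0.011, 0.05995], times=[0.0, 4.0], nh4=[50.0, 0.0])
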