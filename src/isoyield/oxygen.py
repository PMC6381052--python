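"""Closed-flask oxygen mass balance for nitrification incubations.

In a sealed serum flask the only oxygen available is the headspace air plus
the dissolved oxygen of the air-saturated mixed liquor.  This module compares
that inventory against the stoichiometric demand of the added nitrogen
substrate and estimates the dissolved-oxygen concentration remaining after
complete oxidation, assuming fast gas-liquid equilibration (so the dissolved
concentration scales with the depleted O2 partial pressure).  Endogenous
respiration and biomass assimilation are deliberately excluded, making the
demand a slight overestimate and the verdict conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .errors import ConfigError, TemperatureRangeError

Conversion = Literal["nitrification_full", "nitritation", "nitratation"]

#: Stoichiometric oxygen demand, g O2 per g N, total oxidation, no assimilation.
O2_PER_N = {
    "nitrification_full": 4.57,  # NH4+ -> NO3-
    "nitritation": 3.43,  # NH4+ -> NO2-
    "nitratation": 1.14,  # NO2- -> NO3-
}

R_L_ATM = 0.082057  # L atm / (mol K)
O2_MOLAR_MASS = 32.0  # g/mol

#: Freshwater dissolved-oxygen air-saturation concentrations (mg O2/L) at
#: 1 atm, 5 degC steps — the classical table used in wastewater-engineering
#: practice; linearly interpolated in between.
DO_SATURATION_TABLE = {
    0: 14.6, 5: 12.8, 10: 11.3, 15: 10.2, 20: 9.2, 25: 8.4, 30: 7.6,
    35: 7.1, 40: 6.6, 45: 6.1, 50: 5.6, 55: 5.2, 60: 4.8,
}


@dataclass
class FlaskSpec:
    """Serum-flask geometry and headspace composition."""

    total_volume: float = 120.0  # mL
    liquid_volume: float = 50.0  # mL
    o2_mole_fraction: float = 0.209
    pressure: float = 1.0  # atm

    def __post_init__(self) -> None:
        if not 0 < self.liquid_volume < self.total_volume:
            raise ValueError("need 0 < liquid_volume < total_volume")

    @property
    def headspace_volume(self) -> float:
        return self.total_volume - self.liquid_volume


@dataclass
class OxygenBalance:
    """Available vs required oxygen in one sealed incubation."""

    required_o2: float  # mg
    headspace_o2: float  # mg
    dissolved_o2_initial: float  # mg
    excess_factor: float  # available / required (inf when required = 0)
    final_do: float  # mg O2 / L after complete oxidation

    @property
    def available_o2(self) -> float:
        return self.headspace_o2 + self.dissolved_o2_initial


def do_saturation(temperature: float) -> float:
    """Air-saturation DO concentration (mg/L) by linear table interpolation."""
    temps = sorted(DO_SATURATION_TABLE)
    if not temps[0] <= temperature <= temps[-1]:
        raise TemperatureRangeError(
            f"temperature {temperature} degC outside table range "
            f"[{temps[0]}, {temps[-1]}]"
        )
    lo = max(t for t in temps if t <= temperature)
    hi = min(t for t in temps if t >= temperature)
    if lo == hi:
        return DO_SATURATION_TABLE[lo]
    w = (temperature - lo) / (hi - lo)
    return (1 - w) * DO_SATURATION_TABLE[lo] + w * DO_SATURATION_TABLE[hi]


def required_oxygen(
    substrate_mg_n_per_l: float, liquid_volume: float, conversion: Conversion
) -> float:
    """Stoichiometric O2 demand (mg) to oxidize the added substrate."""
    if conversion not in O2_PER_N:
        raise ConfigError(f"unknown conversion {conversion!r}")
    if substrate_mg_n_per_l < 0 or liquid_volume <= 0:
        raise ValueError("substrate and liquid volume must be positive")
    return O2_PER_N[conversion] * substrate_mg_n_per_l * liquid_volume / 1000.0


def available_oxygen(
    flask: FlaskSpec, temperature: float, *, gas_temperature: float | None = None
) -> tuple[float, float]:
    """Headspace and dissolved oxygen (mg) at the incubation temperature.

    Headspace O2 by the ideal-gas law, by default at the incubation
    temperature (``gas_temperature`` overrides, e.g. to quantify the gas at a
    lab fill temperature); dissolved O2 at air saturation for the incubation
    temperature.
    """
    t_gas = temperature if gas_temperature is None else gas_temperature
    t_kelvin = t_gas + 273.15
    moles = (
        flask.o2_mole_fraction
        * flask.pressure
        * (flask.headspace_volume / 1000.0)
        / (R_L_ATM * t_kelvin)
    )
    headspace_mg = moles * O2_MOLAR_MASS * 1000.0
    dissolved_mg = do_saturation(temperature) * flask.liquid_volume / 1000.0
    return headspace_mg, dissolved_mg


def oxygen_balance(
    flask: FlaskSpec,
    substrate_mg_n_per_l: float,
    temperature: float,
    conversion: Conversion,
    *,
    gas_temperature: float | None = None,
) -> OxygenBalance:
    """Full oxygen budget of one sealed incubation.

    The post-oxidation dissolved concentration assumes fast re-equilibration:
    both headspace and dissolved inventories scale linearly with the O2
    partial pressure, so ``final_do = saturation(T) * remaining / initial``.
    """
    req = required_oxygen(substrate_mg_n_per_l, flask.liquid_volume, conversion)
    headspace, dissolved = available_oxygen(
        flask, temperature, gas_temperature=gas_temperature
    )
    total = headspace + dissolved
    sat = do_saturation(temperature)
    if req == 0:
        return OxygenBalance(
            required_o2=0.0,
            headspace_o2=headspace,
            dissolved_o2_initial=dissolved,
            excess_factor=math.inf,
            final_do=sat,
        )
    remaining = max(total - req, 0.0)
    return OxygenBalance(
        required_o2=req,
        headspace_o2=headspace,
        dissolved_o2_initial=dissolved,
        excess_factor=total / req,
        final_do=sat * remaining / total,
    )
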