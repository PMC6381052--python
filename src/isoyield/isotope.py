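"""Isotope mixing model for bulk-biomass :sup:`13`\\ C enrichment.

A nitrifying community grows on labelled bicarbonate (atom fraction
``a_medium``, typically 0.99) while the pre-existing biomass carbon sits at
natural abundance (~0.011).  New biomass carbon therefore enters at the medium
abundance, and the measured bulk atom fraction of the biomass is a two-pool
mixture of old and new carbon.  Inverting that mixture interval by interval
gives the fraction of new biomass per interval (``f_n``), the per-interval
growth factor (``f_g = f_n / (1 - f_n)``), and a reconstructed biomass (VSS)
trajectory from the measured initial concentration.

Atom fractions are handled as fractions in [0, 1] throughout; percent values
are converted at the I/O boundary.  Carbon atom fractions and carbon mass
fractions are treated interchangeably (the 12C/13C mass difference is
ignored), a deliberate modelling simplification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import (
    DegenerateMixingError,
    FormulaParseError,
    InsufficientDataError,
    InvalidGrowthError,
    UndefinedGrowthError,
)

#: Natural 13C abundance of unlabelled biomass carbon (atom fraction).
NATURAL_ABUNDANCE = 0.011

#: Default carbon content of biomass, g C per g VSS, from the C5H7O2N
#: empirical composition of activated sludge.
DEFAULT_CARBON_FRACTION = 0.531

#: Standard atomic masses (g/mol) used by :func:`carbon_mass_fraction`.
ATOMIC_MASSES = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}

Substrate = Literal["ammonium", "nitrite"]


@dataclass(frozen=True)
class IsotopeTimePoint:
    """Bulk-biomass 13C atom fraction at one sampling time (hours)."""

    time: float
    a13C: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")
        if not 0.0 <= self.a13C <= 1.0:
            raise ValueError(f"a13C must be in [0, 1], got {self.a13C}")


@dataclass(frozen=True)
class ChemTimePoint:
    """Ammonium-N and nitrite-N concentrations (mg N/L) at one time (hours)."""

    time: float
    nh4_n: float
    no2_n: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")
        if self.nh4_n < 0 or self.no2_n < 0:
            raise ValueError("concentrations must be non-negative")


def _check_strictly_increasing(times: Sequence[float], what: str) -> None:
    t = np.asarray(times, dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{what} sampling times must be strictly increasing")


@dataclass
class IncubationReplicate:
    """One flask: paired isotope and chemistry time series with metadata.

    Parameters
    ----------
    isotope_series:
        At least two bulk 13C measurements (the first at or near t=0 anchors
        the natural-abundance baseline).
    chem_series:
        Substrate concentrations over time; the grid need not coincide with
        the isotope grid.
    vss0:
        Initial biomass concentration, g VSS/L.
    substrate:
        ``"ammonium"`` (total AOB/AOA + NOB growth) or ``"nitrite"`` (NOB
        growth only).
    temperature:
        Incubation temperature, deg C.
    a13C_medium:
        Atom fraction of the labelled bicarbonate pool (label purity).
    carbon_fraction:
        g C per g VSS of the biomass.
    """

    isotope_series: list[IsotopeTimePoint]
    chem_series: list[ChemTimePoint]
    vss0: float
    substrate: Substrate
    temperature: float
    a13C_medium: float = 0.99
    carbon_fraction: float = DEFAULT_CARBON_FRACTION
    replicate_id: str = "rep"

    def __post_init__(self) -> None:
        if len(self.isotope_series) < 2:
            raise InsufficientDataError("need >= 2 isotope time points")
        if self.vss0 <= 0:
            raise ValueError(f"vss0 must be > 0, got {self.vss0}")
        if not 0.0 < self.a13C_medium <= 1.0:
            raise ValueError("a13C_medium must be in (0, 1]")
        if not 0.0 < self.carbon_fraction < 1.0:
            raise ValueError("carbon_fraction must be in (0, 1)")
        _check_strictly_increasing([p.time for p in self.isotope_series], "isotope")
        _check_strictly_increasing([p.time for p in self.chem_series], "chemistry")
        if self.isotope_series[0].a13C >= self.a13C_medium:
            raise DegenerateMixingError(
                "initial biomass abundance is not below the medium abundance; "
                "label uptake cannot be detected"
            )

    @property
    def isotope_times(self) -> np.ndarray:
        return np.array([p.time for p in self.isotope_series])

    @property
    def a13C_values(self) -> np.ndarray:
        return np.array([p.a13C for p in self.isotope_series])


@dataclass
class BiomassTrajectory:
    """Reconstructed biomass concentrations plus per-interval diagnostics.

    ``f_n_series`` and ``f_g_series`` have one entry per interval, i.e. one
    fewer than ``times``/``vss``.
    """

    times: np.ndarray
    vss: np.ndarray
    f_n_series: np.ndarray
    f_g_series: np.ndarray
    clamped_intervals: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vss = np.asarray(self.vss, dtype=float)
        self.f_n_series = np.asarray(self.f_n_series, dtype=float)
        self.f_g_series = np.asarray(self.f_g_series, dtype=float)
        if not (len(self.times) == len(self.vss) == len(self.f_n_series) + 1):
            raise ValueError("inconsistent trajectory lengths")


def fraction_new_biomass(a_prev: float, a_curr: float, a_medium: float) -> float:
    """Fraction of the biomass at the end of an interval that is newly grown.

    Inverts the two-pool mixture: old carbon at ``a_prev``, new carbon at the
    medium abundance ``a_medium``::

        f_n = (a_curr - a_prev) / (a_medium - a_prev)

    Negative values (``a_curr < a_prev``) are returned as-is here; clamping of
    small negative excursions is the caller's policy (see
    :func:`biomass_trajectory`).
    """
    if a_medium <= a_prev:
        raise DegenerateMixingError(
            f"a_medium ({a_medium}) must exceed a_prev ({a_prev}); "
            "label indistinguishable from biomass"
        )
    if not 0.0 <= a_curr <= 1.0:
        raise ValueError(f"a_curr must be in [0, 1], got {a_curr}")
    return (a_curr - a_prev) / (a_medium - a_prev)


def growth_factor(f_n: float) -> float:
    """Per-interval relative biomass increase ``f_g = f_n / (1 - f_n)``.

    Equals ``dVSS / VSS_prev`` under the mixing model.
    """
    if f_n >= 1.0:
        raise UndefinedGrowthError(f"f_n must be < 1, got {f_n}")
    return f_n / (1.0 - f_n)


def forward_mix(
    vss_prev: float, a_prev: float, delta_vss: float, a_medium: float
) -> float:
    """Bulk atom fraction after adding ``delta_vss`` of new biomass.

    Forward counterpart of :func:`fraction_new_biomass`, used as an
    independent oracle: the carbon-weighted mean of the old pool at ``a_prev``
    and the new pool at ``a_medium``.
    """
    if vss_prev <= 0:
        raise ValueError(f"vss_prev must be > 0, got {vss_prev}")
    if delta_vss < 0:
        raise InvalidGrowthError(f"delta_vss must be >= 0, got {delta_vss}")
    return (vss_prev * a_prev + delta_vss * a_medium) / (vss_prev + delta_vss)


def biomass_trajectory(
    replicate: IncubationReplicate,
    *,
    a_medium_series: Sequence[float] | None = None,
    clamp_negative: bool = True,
    vss0_override: float | None = None,
) -> BiomassTrajectory:
    """Reconstruct the VSS trajectory from the measured 13C series.

    The inversion is chained: each interval uses the previous *measured* atom
    fraction as the old-pool abundance, so

        ``vss[n] = vss[n-1] * (1 + f_g[n])``

    with ``f_n[n]`` computed between consecutive measurements.

    Parameters
    ----------
    a_medium_series:
        Optional per-interval effective medium abundance (one value per
        interval), used by the decay correction.  Defaults to the replicate's
        constant ``a13C_medium``.
    clamp_negative:
        Clamp slightly negative ``f_n`` (IRMS noise) to zero.  Clamped
        interval indices are recorded on the returned trajectory.  Set False
        to keep negative values for diagnostics.
    vss0_override:
        Use this initial VSS instead of the replicate's (sensitivity runs).
    """
    a = replicate.a13C_values
    times = replicate.isotope_times
    n_int = len(a) - 1
    if a_medium_series is None:
        a_med = np.full(n_int, replicate.a13C_medium)
    else:
        a_med = np.asarray(a_medium_series, dtype=float)
        if a_med.shape != (n_int,):
            raise ValueError(
                f"a_medium_series must have one value per interval ({n_int})"
            )

    vss0 = replicate.vss0 if vss0_override is None else vss0_override
    vss = np.empty(len(a))
    vss[0] = vss0
    f_n = np.empty(n_int)
    f_g = np.empty(n_int)
    clamped: list[int] = []
    for i in range(n_int):
        try:
            fn = fraction_new_biomass(a[i], a[i + 1], a_med[i])
        except DegenerateMixingError as exc:
            raise DegenerateMixingError(f"interval {i}: {exc}") from exc
        if fn < 0 and clamp_negative:
            fn = 0.0
            clamped.append(i)
        try:
            fg = growth_factor(fn)
        except UndefinedGrowthError as exc:
            raise UndefinedGrowthError(f"interval {i}: {exc}") from exc
        f_n[i] = fn
        f_g[i] = fg
        vss[i + 1] = vss[i] * (1.0 + fg)

    return BiomassTrajectory(
        times=times, vss=vss, f_n_series=f_n, f_g_series=f_g,
        clamped_intervals=clamped,
    )


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def carbon_mass_fraction(formula: str) -> float:
    """Carbon mass fraction of an empirical C/H/O/N biomass formula.

    >>> round(carbon_mass_fraction("C5H7O2N"), 3)
    0.531
    """
    formula = formula.strip()
    if not formula:
        raise FormulaParseError("empty formula")
    pos = 0
    counts: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaParseError(f"cannot parse formula {formula!r}")
        pos = match.end()
        elem, num = match.group(1), match.group(2)
        if elem not in ATOMIC_MASSES:
            raise FormulaParseError(f"unsupported element {elem!r} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise FormulaParseError(f"cannot parse formula {formula!r}")
    total = sum(ATOMIC_MASSES[e] * n for e, n in counts.items())
    return ATOMIC_MASSES["C"] * counts.get("C", 0) / total
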