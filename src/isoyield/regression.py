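"""Yield estimation: biomass produced per unit nitrogen oxidized.

The reconstructed biomass concentration is regressed against consumed
substrate nitrogen (N0 - N(t)); the slope of the ordinary least-squares fit is
the maximum biomass yield Y_max (g VSS per g N), growth only, decay neglected.
Replicate slopes are averaged (mean +/- sample sd), and the ammonia-oxidizer
yield is obtained by subtracting the NOB yield (nitrite flasks) from the total
nitrifier yield (ammonium flasks), since nitrite oxidation proceeds in both.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidPerturbationError,
    PairingError,
    UndefinedSlopeError,
)
from .isotope import (
    BiomassTrajectory,
    ChemTimePoint,
    IncubationReplicate,
    Substrate,
    biomass_trajectory,
)

Guild = Literal["total_nitrifier", "aoboa", "nob"]


@dataclass
class YieldEstimate:
    """Slope-based Y_max with dispersion and condition labels."""

    y_max: float
    sd: float
    n_replicates: int
    r_squared: float
    guild: Guild
    substrate: Substrate
    temperature: float
    scenario: str = "none"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must be in [0, 1]")
        if self.guild == "nob" and self.substrate != "nitrite":
            raise ValueError("NOB yield must come from a nitrite incubation")


@dataclass
class ReplicateFit:
    """Per-replicate regression result."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    interpolated: bool  # nitrogen interpolated onto the isotope grid


def consumed_nitrogen(
    chem_series: Sequence[ChemTimePoint],
    times: np.ndarray,
    substrate: Substrate,
) -> tuple[np.ndarray, bool]:
    """Consumed substrate-N (mg N/L) at each requested time.

    Returns ``(N0 - N(t), interpolated)``; nitrogen is linearly interpolated
    where the chemistry grid lacks a measurement at an isotope sampling time.
    """
    if len(chem_series) < 2:
        raise InsufficientDataError("need >= 2 chemistry time points")
    chem_t = np.array([p.time for p in chem_series])
    conc = np.array(
        [p.nh4_n if substrate == "ammonium" else p.no2_n for p in chem_series]
    )
    interpolated = not np.all(np.isin(np.round(times, 9), np.round(chem_t, 9)))
    n_at = np.interp(times, chem_t, conc)
    return n_at[0] - n_at, interpolated


def fit_replicate_yield(
    trajectory: BiomassTrajectory,
    chem_series: Sequence[ChemTimePoint],
    substrate: Substrate,
    *,
    through_origin: bool = False,
) -> ReplicateFit:
    """OLS slope of VSS (g/L) against consumed N (g/L) for one flask.

    Consumed nitrogen is treated as error-free (the spectrophotometric error
    is far smaller than the VSS error).  With ``through_origin`` the line is
    forced through (0, vss0); by default the intercept is fitted, absorbing
    any offset at t0.
    """
    consumed_mg, interpolated = consumed_nitrogen(
        chem_series, trajectory.times, substrate
    )
    x = consumed_mg / 1000.0  # g N / L, same mass units as VSS
    y = trajectory.vss
    if len(x) < 2:
        raise InsufficientDataError("need >= 2 paired (biomass, nitrogen) points")
    if np.ptp(x) == 0:
        raise UndefinedSlopeError("no nitrogen was consumed; slope undefined")

    if through_origin:
        x0 = x - x[0]
        y0 = y - y[0]
        slope = float(np.dot(x0, y0) / np.dot(x0, x0))
        intercept = float(y[0])
        resid = y0 - slope * x0
        ss_tot = float(np.dot(y0, y0))
        r_squared = 1.0 if ss_tot == 0 else 1.0 - float(np.dot(resid, resid)) / ss_tot
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r_squared = float(res.rvalue) ** 2
    if slope < 0:
        warnings.warn(
            f"negative fitted yield slope ({slope:.4g} g VSS/g N); reported as-is",
            stacklevel=2,
        )
    r_squared = min(max(r_squared, 0.0), 1.0)
    return ReplicateFit(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        n_points=len(x),
        interpolated=interpolated,
    )


def aggregate_replicates(
    slopes: Sequence[float],
    *,
    guild: Guild,
    substrate: Substrate,
    temperature: float,
    r_squared: float = 1.0,
    scenario: str = "none",
) -> YieldEstimate:
    """Mean and sample sd over replicate slopes (sd = 0 for a single flask)."""
    if len(slopes) == 0:
        raise InsufficientDataError("no replicate slopes to aggregate")
    arr = np.asarray(slopes, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return YieldEstimate(
        y_max=float(arr.mean()),
        sd=sd,
        n_replicates=len(arr),
        r_squared=r_squared,
        guild=guild,
        substrate=substrate,
        temperature=temperature,
        scenario=scenario,
    )


def estimate_yield(
    replicates: Iterable[IncubationReplicate],
    *,
    through_origin: bool = False,
    scenario: str = "none",
) -> YieldEstimate:
    """Full per-replicate pipeline: invert isotopes, fit, aggregate.

    All replicates must share substrate and temperature.  The reported
    r_squared is the mean across replicates.
    """
    reps = list(replicates)
    if not reps:
        raise InsufficientDataError("no replicates")
    substrate = reps[0].substrate
    temperature = reps[0].temperature
    for r in reps:
        if r.substrate != substrate or r.temperature != temperature:
            raise PairingError("replicates mix substrates or temperatures")
    fits = [
        fit_replicate_yield(
            biomass_trajectory(r), r.chem_series, substrate,
            through_origin=through_origin,
        )
        for r in reps
    ]
    guild: Guild = "nob" if substrate == "nitrite" else "total_nitrifier"
    return aggregate_replicates(
        [f.slope for f in fits],
        guild=guild,
        substrate=substrate,
        temperature=temperature,
        r_squared=float(np.mean([f.r_squared for f in fits])),
        scenario=scenario,
    )


def subtract_nob(total: YieldEstimate, nob: YieldEstimate) -> YieldEstimate:
    """Ammonia-oxidizer yield: total (ammonium flasks) minus NOB (nitrite).

    Standard deviations combine in quadrature.  A negative difference is
    reported with a warning, not clamped.
    """
    if total.substrate != "ammonium" or nob.substrate != "nitrite":
        raise PairingError(
            "total must come from ammonium and nob from nitrite incubations"
        )
    if total.temperature != nob.temperature:
        raise PairingError(
            f"temperature mismatch: {total.temperature} vs {nob.temperature}"
        )
    y = total.y_max - nob.y_max
    if y < 0:
        warnings.warn(
            f"negative ammonia-oxidizer yield ({y:.4g}); "
            "NOB yield exceeds the total",
            stacklevel=2,
        )
    return YieldEstimate(
        y_max=y,
        sd=math.hypot(total.sd, nob.sd),
        n_replicates=min(total.n_replicates, nob.n_replicates),
        r_squared=min(total.r_squared, nob.r_squared),
        guild="aoboa",
        substrate="ammonium",
        temperature=total.temperature,
        scenario=total.scenario,
    )


def sensitivity_initial_biomass(
    replicates: Sequence[IncubationReplicate],
    perturbations: Sequence[float] = (0.9, 1.0, 1.1),
    *,
    through_origin: bool = False,
) -> dict[float, YieldEstimate]:
    """Re-estimate Y_max with the initial VSS scaled by each factor.

    The whole inversion is homogeneous of degree one in vss0, so on noiseless
    data the yield scales exactly with the factor; this mirrors the bounded
    +/-10 % effect of an initial-biomass measurement error.
    """
    results: dict[float, YieldEstimate] = {}
    for factor in perturbations:
        if factor <= 0:
            raise InvalidPerturbationError(f"factor must be > 0, got {factor}")
        reps = list(replicates)
        substrate = reps[0].substrate
        fits = []
        for r in reps:
            traj = biomass_trajectory(r, vss0_override=r.vss0 * factor)
            fits.append(
                fit_replicate_yield(
                    traj, r.chem_series, substrate, through_origin=through_origin
                )
            )
        guild: Guild = "nob" if substrate == "nitrite" else "total_nitrifier"
        results[factor] = aggregate_replicates(
            [f.slope for f in fits],
            guild=guild,
            substrate=substrate,
            temperature=reps[0].temperature,
            r_squared=float(np.mean([f.r_squared for f in fits])),
            scenario=f"vss0 x {factor:g}",
        )
    return results
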