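# Methods

## The measurement principle

Nitrifiers are autotrophs: every gram of biomass they synthesize draws its
carbon from the dissolved inorganic carbon (DIC) pool. If that pool is
supplied as 99 % `13C`-labelled bicarbonate while the pre-existing biomass
carbon sits at natural abundance (a13C ≈ 0.011), carbon fixation leaves a
direct isotopic fingerprint: the bulk `13C` atom fraction of the biomass is a
two-pool mixture of old and new carbon. In a short batch incubation with a
known nitrogen substrate (ammonium or nitrite), tracking that atom fraction
alongside the substrate concentration yields the maximum biomass yield

    Y_max = d[VSS] / d[N consumed]   (g VSS per g N)

without enrichment, isolation, or sophisticated on-line sensors.

## The inversion (isotope → biomass)

For each interval between consecutive isotope measurements,

    f_n = (a_tn − a_tn−1) / (a_medium − a_tn−1)      fraction of new biomass
    f_g = f_n / (1 − f_n)                            growth factor, ΔVSS/VSS
    VSS_tn = VSS_tn−1 · (1 + f_g)

The inversion is *chained*: each interval uses the previous measured atom
fraction as the old-pool abundance, so measurement information is never
reused. Assumptions:

- growth is the only process changing the bulk abundance (decay removes
  carbon at the bulk abundance and is invisible to the isotope signal);
- new carbon enters at the medium abundance (label purity 0.99 by default);
- `13C` atom fractions and carbon *mass* fractions are used interchangeably —
  the 12C/13C mass difference (~8 %) cancels to first order in the mixing
  ratio and is ignored, as is standard in bulk-EA-IRMS budgets;
- atom fractions are stored in [0, 1]; percent values are converted at the
  I/O boundary only.

Slightly negative `f_n` (IRMS noise, absolute σ ≈ 5·10⁻⁶ on the atom
fraction) is clamped to zero by default because negative growth is
unphysical under the neglect-decay assumption; the clamped interval indices
are recorded and a diagnostics mode keeps the raw negative values.

## Yield regression and guild separation

Reconstructed VSS is regressed on consumed substrate nitrogen
(N₀ − N(t), converted to g/L) by ordinary least squares with a fitted
intercept. Consumed N is treated as error-free: the spectrophotometric
nitrogen assays are far more precise than the initial-VSS determination,
which carries 0.6–9.9 % relative error. If an isotope sampling time lacks a
chemistry measurement, nitrogen is linearly interpolated (flagged in the
fit result). A through-origin mode is available but not the default — the
free intercept absorbs washing and t₀ offsets.

Replicates (typically triplicate flasks) are fitted separately and
aggregated as mean ± sample standard deviation; pooled fitting is possible
through the same interface but is not the default convention. Ammonium
incubations measure the *total* nitrifier yield (ammonia oxidizers plus the
nitrite oxidizers consuming the produced nitrite); nitrite incubations
measure the NOB yield alone; the ammonia-oxidizer (AOB/AOA) yield is the
difference, with standard deviations combined in quadrature. Negative
differences are reported with a warning, never clamped.

Because the whole inversion is homogeneous of degree one in the initial
biomass concentration, scaling vss0 by a factor k scales the fitted slope by
exactly k. The ±10 % initial-biomass sensitivity analysis is therefore an
exact ±10 % band on Y_max — implemented as a re-run, verified as an identity.

## Decay scenarios

Decay respires mostly-unlabelled biomass carbon into the small labelled DIC
pool (71.5 mg C/L from 0.5 g/L NaHCO₃) and lowers the effective label
purity over time, which biases the uncorrected yield *downward*. Two
bracketing corrections re-run the inversion with a time-varying medium
abundance:

- **death_regeneration** (most probable): decayed COD splits into 8 %
  particulate products and 92 % slowly biodegradable substrate; of the
  biodegradable share a heterotrophic yield Y_H (0.67 mesophilic, 0.75
  thermophilic) is re-assimilated, so only `0.92·(1 − Y_H)` of the decayed
  carbon is respired into the pool.
- **all_to_co2** (worst case): all decayed carbon is respired.

Bookkeeping is stepwise per sampling interval (Euler, optional sub-stepping
for convergence checks): decayed carbon = C_bio(t)·(1 − e^(−b·Δt)) at the
biomass's current bulk abundance, pool abundance updated as a
carbon-weighted mean. Decay rates default to 0.15 / 0.38 / 0.40 d⁻¹ at
15 / 28 / 50 °C. The pool is treated as sealed (no headspace CO₂ exchange,
rubber-stoppered flasks, short incubations) and is not depleted by growth
uptake in the correction (uptake at the pool abundance does not change the
abundance; the mass effect is second-order for these pool sizes).

Interval convention: growth during interval n draws on the pool as diluted
by the *preceding* intervals, so the inversion of interval n uses the pool
abundance at the interval's start. (Using the end-of-interval abundance
systematically overcorrects by one interval's dilution; this was verified
against forward simulations with known decay, where the matched correction
must recover the true yield more accurately than the uncorrected estimate —
it does, roughly halving the Monte-Carlo error.) An endpoint-only mode
(final abundance applied to all intervals) is provided as an upper bound.

The COD↔VSS conversion is fixed at the standard activated-sludge value of
1.42 g COD/g VSS and exposed as a parameter.

### Heterotrophic share of the labelled biomass

Heterotrophs feeding on nitrifier decay products re-assimilate some labelled
carbon, so a small part of the measured `13C` gain is heterotrophic growth.
The implemented estimate integrates, per interval, the labelled carbon pool
present × the decayed fraction × biodegradable fraction × Y_H, relative to
the total labelled carbon produced. At nitrifier decay rates of
0.03–0.06 d⁻¹ and a 4 h incubation this gives ≈ 0.17–0.34 %, i.e. a few
tenths of a percent overestimation of the autotrophic yield; over a 21.5 h
incubation it can reach ~1.6 %. The formula is one defensible reading of
this budget and is validated to order of magnitude only.

## Closed-flask oxygen feasibility

120 mL serum flasks with 50 mL liquid are sealed, so the oxygen inventory is
the 70 mL air headspace (ideal gas, 20.9 % O₂, 1 atm, quantified at the
incubation temperature; a fill-temperature mode exists) plus the dissolved
oxygen of the air-saturated liquid. Demand uses the classical total-oxidation
stoichiometry without assimilation: 4.57 g O₂/g N (NH₄⁺→NO₃⁻), 3.43
(NH₄⁺→NO₂⁻), 1.14 (NO₂⁻→NO₃⁻). Endogenous respiration is excluded.

Dissolved-oxygen saturation comes from the classical freshwater
air-saturation table used in wastewater-engineering practice (5 °C steps,
linear interpolation; 10.2 / 7.92 / 5.6 mg/L at 15 / 28 / 50 °C). Limnology
correlations give values ~1–2 % lower at the warm end; the table is a
module-level constant and easy to swap.

After complete oxidation both inventories scale linearly with the O₂
partial pressure, so the re-equilibrated dissolved concentration is
`saturation(T) × remaining / initial`. For the 50 mg N/L ammonium
incubations this gives excess factors 1.78 / 1.69 / 1.57 and post-oxidation
DO of 4.46 / 3.24 / 2.03 mg/L at 15 / 28 / 50 °C — oxygen is never
limiting, with the 50 °C flask the tightest case.

## The simulator

The forward model generates what the analysis assumes: zero-order substrate
oxidation to depletion (batch incubations of these communities show linear
substrate profiles), gross growth ΔVSS = Y·ΔN with new carbon entering at
the current DIC-pool abundance, optional first-order decay with respired
carbon diluting the pool (and an optional fraction re-assimilated as
heterotrophic biomass), and independent Gaussian noise: σ = 5·10⁻⁶ absolute
on atom fractions (IRMS), 9.9 % relative on the measured initial VSS (the
worst of the reported 0.6–9.9 % technical-replicate errors), 0.5 mg N/L on
the nitrogen assays. Measurement *times* are noiseless. Carbon is conserved
exactly across the growth/decay bookkeeping (growth draws on the DIC pool).

Three presets encode the study-like campaigns — 21.5 h at 15 °C, 8 h at
28 °C, 4 h at 50 °C, five samples each, 50 mg N/L depleted at the end of the
window, ~1 g VSS/L inoculum, with total/NOB yields of 0.161/0.051,
0.108/0.048 and 0.245/0.025 g VSS/g N respectively.

What the simulator does **not** emulate: Monod rate saturation (zero-order
only by default), pH drift, transient nitrite accumulation in ammonium
flasks, autocorrelated instrument drift, non-nitrifier autotrophic fixation,
or abundance-dependent community dynamics. Passing recovery tests therefore
demonstrate correctness of the inversion and fitting under the method's own
error model — not robustness to every failure mode of real incubations.

## Numerical choices and degenerate inputs

- Atomic masses fixed (C 12.011, H 1.008, O 15.999, N 14.007) so the
  carbon-fraction of C₅H₇O₂N is bit-stable at 0.5309.
- `a_medium ≤ a_prev` raises a degenerate-mixing error naming the interval;
  `f_n ≥ 1` raises an undefined-growth error.
- Zero nitrogen consumption raises an undefined-slope error rather than
  returning NaN; zero required oxygen reports an infinite excess factor.
- Replicate aggregation uses the sample standard deviation (ddof = 1),
  zero for a single flask.
- Seeds: one integer seed per simulated experiment drives all replicates
  and noise draws through a single `numpy` generator; identical seeds give
  bit-identical experiments.

## Problem sizes

Monte-Carlo checks use 200 simulated triplicate experiments for parameter
recovery and 100 for the decay forward/inverse comparison; each experiment
is a 5-point triplicate, so the full test suite runs in seconds. The
acceptance script re-runs 50 experiments per condition and reports medians;
these sizes give stable medians (Monte-Carlo error well below the reported
precision) at negligible cost.

## Known limitations

- The method measures autotrophic carbon-fixation activity; label routed to
  heterotrophs via soluble microbial products (above) and non-nitrifier
  autotrophic pathways (~6–8 % in inhibited controls) bias it slightly
  upward. No correction is applied for the latter.
- AOB and AOA cannot be distinguished when they co-occur; the subtraction
  design separates ammonia oxidizers from nitrite oxidizers only.
- The decay corrections depend on literature decay rates and heterotrophic
  yields, not on measurements from the incubation itself.
- The delta-method uncertainties in the abundance arithmetic ignore
  amplicon-fraction uncertainty unless supplied and are approximate.
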