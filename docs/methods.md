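# Methods

## Model overview

`napus` simulates potential (water-unlimited by default) production of
winter oilseed rape on a daily time step, following the WOFOST scheme:

1. **Phenology.** Development stage DVS runs from 0 (emergence) through 1
   (flowering) to 2 (maturity), driven by effective temperature
   max(0, T̄ − TBASE) accumulated against the thermal totals TSUM1
   (emergence → flowering) and TSUM2 (flowering → maturity). Emergence
   itself consumes TSUMEM degree-days above TBASEM from sowing.
2. **Light and assimilation.** Daily gross CO₂ assimilation integrates the
   single-leaf response A = AMAX·(1 − exp(−EFF·I/AMAX)) over canopy depth
   and over the daylight period with three-point Gaussian quadrature.
   Instantaneous PAR at the canopy top follows the standard sine-elevation
   distribution of daily global radiation (PAR fraction 0.5, canopy
   reflection 0.08); light is attenuated exponentially with the extinction
   coefficient KDIFTB(DVS) through the **total** photosynthetic area.
   AMAX is modulated by the temperature table TMPFTB evaluated at daytime
   temperature. Gross CO₂ converts to CH₂O by 30/44.
3. **Respiration and partitioning.** Maintenance costs Σ RMx·Wx scale with
   Q10 = 2 around 25 °C and are capped at gross assimilation. The root
   fraction FRTB(DVS) is taken off first; the shoot remainder is split by
   the FLTB/FSTB/FOTB triplet (constrained to sum to 1 at every DVS) and
   converted to dry matter with the organ efficiencies CVL/CVS/CVO/CVR.
   This structure closes the daily carbon ledger identically:
   gross − maintenance = Σ ΔWx/CVx, which the tests verify to 1e-9
   relative on every day of every seeded run.
4. **Leaves.** Leaf mass enters daily cohorts. In the juvenile phase
   (DVS < 0.3) area grows exponentially at RGRLAI per effective
   degree-day, capped by source supply ΔW_leaf·SLATB(DVS); afterwards
   growth is purely source-driven. Cohorts age by
   (T̄ − TBASE)/(T_ref − TBASE) physiological days and die past SPAN,
   moving their mass to the dead-leaf pool.
5. **Pods.** From flowering, pod area index PAI = SPA·(W_so − W_so@DVS=1)
   joins the canopy, and TPAI = LAI + PAI drives interception. Storage
   mass accumulated *before* flowering is treated as buds and flowers and
   carries no photosynthetic area: the published allocation tables route
   assimilate to storage organs from DVS 0, and charging that early mass
   with pod area would contradict the field protocol in which siliques are
   absent at the first three measurement stages. When no storage mass
   exists before flowering the expression reduces to the plain product
   SPA·W_so. A `tpai_interception=False` switch restricts interception to
   leaves, reproducing the classical LAI-driven model; with SPA = 0 the
   two modes coincide exactly (regression-tested).
6. **Water.** A single-layer bucket (initial storage WAV, capacity 80 cm)
   gains rainfall and loses Hargreaves reference evapotranspiration split
   into crop transpiration and soil evaporation by canopy cover. In
   water-limited mode a stress factor (linear below half capacity)
   multiplies the next day's gross assimilation; in potential mode the
   factor is 1 but the bucket still runs and its ledger closes daily.

## Parameters

Published single-point values (means with calibration ranges) cover WAV,
TSUM1, TSUM2, TDWI, SPA, SPAN, the four conversion efficiencies, and the
staged allocation triplet; they ship in
`src/napus/data/crop_parameters.yaml` together with the wide screening
bounds used for sensitivity analysis. The allocation means at DVS 0.7 sum
to 1.01; they are renormalised onto the simplex on load, as are all drawn
triplets. Validation accepts the union of the two published ranges where
they disagree (TDWI: screening bound 10 vs single-point maximum 13).

Everything the published tables do not fix is a package default chosen
once for a subtropical winter rape stand and declared here:

| parameter | default | reasoning |
| --- | --- | --- |
| TBASE | 5 °C | development base; places flowering in late February and maturity in early May, matching the observed stage calendar |
| TSUMEM, TBASEM | 25 °C·d, 3 °C | rapid autumn emergence |
| LAIEM | 0.015 | initial leaf mass (≈0.94·0.6·TDWI) × juvenile SLA |
| RGRLAI | 0.012 (°C·d)⁻¹ | juvenile exponential expansion rate |
| SLATB | 0.0030 → 0.0020 ha·kg⁻¹ | young rape leaves are thin; SLA declines with age |
| KDIFTB | 0.60 → 0.75 | denser, more horizontal canopy late in the season |
| EFFTB | 0.45 kg·ha⁻¹·h⁻¹/(J·m⁻²·s⁻¹) | standard single-leaf initial light-use efficiency |
| AMAXTB | 35 → 15 kg·ha⁻¹·h⁻¹ | photosynthetic capacity declining towards maturity |
| RML/RMO/RMR/RMS | 0.030/0.010/0.015/0.015 | WOFOST-typical maintenance coefficients |
| FRTB | 0.40 at DVS 0 → 0 at 1.3 | roots exist (CVR, RMR are published) but are not observed; standard declining root share |
| senescence reference | 20 °C | SPAN is the leaf life span in days at 20 °C; ageing scales as (T̄−TBASE)/(20−TBASE). A warm-climate 35 °C reference would make winter leaves nearly immortal and delay the LAI peak past the milky stage, contradicting the observed leaf-to-pod canopy succession |

With these defaults and the published means the engine produces LAI peaking
near 2.7–3.4 around flowering, TPAI up to ≈4.5, storage-organ yield (TWSO)
of 2–6 t·ha⁻¹ and above-ground biomass ≈10 t·ha⁻¹ — field-realistic
magnitudes for the region emulated. Removing pod photosynthesis (leaf-only
interception, identical parameters) lowers TWSO by ≈2–13% and TAGP by
≈12–38% depending on weather and truth draw; this is the structural effect
the TPAI calibration methods exist to capture.

## Calibration methods

**Phenology.** TSUM1/TSUM2 are estimated from the flowering stage date and
the harvest date as accumulated effective temperature, using the midpoint
of the accumulations to the stage day and to the previous day (a stage
date marks the first day the threshold was reached, so the true total lies
between the two); estimates are clamped to the published ranges with a
warning. Because stage dates quantise thermal time to whole days, the
estimate carries ±half a day's effective temperature of irreducible error;
this leaves a small (~3e-3 area-index RMSE) floor in noise-free twin
experiments that no non-phenology parameter can cancel. Letting the
optimizer polish TSUMs is supported (`refine_phenology=True`) but off by
default: whole-day crossings give finite-difference gradients of poor
quality.

**Baseline (LAI method).** Leaf-only interception; bounded trust-region
least squares of simulated vs observed LAI at the stage dates. The default
free set is the leaf-area parameter SLATB0.00 alone: staged LAI
observations identify canopy-area parameters only, and freeing optical or
source/yield parameters lets them drift along equifinal directions that
the LAI objective cannot resolve. All other parameters keep their initial
values, as a practitioner calibrating a cereal-style model would do.

**TPAI-SPA.** (a) phenology as above; (b) a line search on SPA from the
preset 0.007 with step 0.0005 (configurable within 0.0005–0.001),
descending while the TPAI misfit at pod-bearing stages improves — the
preset exceeds the published SPA maximum 0.0009, so the search in practice
descends and the result is clamped into the published range; (c) bounded
least squares of the sensitive set (KDIFTB2.00, EFFTB0.00, SPA, FSTB1.70,
CVO, EFFTB40.00, SLATB0.00; members with degenerate published ranges are
dropped) against the staged TPAI observations. Because many parameter
combinations produce the same TPAI trajectory, the fitting residual vector
also includes mean-normalised staged TWSO and TAGP residuals — the
conversion and allocation parameters are adjusted on the basis of the
yield at each time point — while the *reported* objective remains the TPAI
RMSE at the stage dates.

**TPAI-Curve.** A step-(a) baseline LAI fit provides the simulated LAI
curve; the calibration curve is the unique quadratic through (x₁) the
simulated LAI peak, valued at the simulated TPAI of that day, (x₂) the
highest TPAI observation strictly between the peak and the final stage,
and (x₃) the final pre-harvest observation, sampled daily and clamped at
zero. Valuing x₁ at TPAI rather than LAI is an intentional
generalisation: it is identical whenever siliques are absent at the LAI
peak, and remains well-behaved when leaf allocation persists past
flowering so that pods already carry area at the peak (the published
allocation tables imply exactly that regime; with the literal LAI value
the interpolating quadratic develops a spurious spike). The sensitive set
is then fitted to minimise the daily RMSE between simulated TPAI and the
curve over [t₁, t₃] plus the pre-t₁ staged LAI residuals (and the same
yield anchoring as above). A raw-provenance curve taken directly from a
daily TPAI trace is also supported (`curve_from_trace`) and is what the
noise-free identifiability twin uses, since the quadratic is an
approximation no parameter set can match exactly.

## Sensitivity analysis

Classic extended FAST: parameter *i* is driven at the maximal frequency
ω = ⌊(n−1)/2M⌋ (M = 4 harmonics) along the search curve
x(s) = ½ + asin(sin(ωs + φ))/π with seeded random phases, the others at
low complementary frequencies; S1 comes from the spectral power at ω and
its harmonics, ST from the complement of the low-frequency band. The
design costs n runs per parameter and enforces n ≥ 65·p. The allocation
triplet is re-mapped row-wise onto the simplex (FL ∈ [0,1],
FS ∈ [0, 1−FL], FO = 1−FL−FS); this sequential-conditional scheme is not
uniform on the simplex and destroys the pure search-curve structure of the
transformed columns, so their indices are flagged `approximate` in the
output rather than silently reported.

## Synthetic data

The weather generator produces a sowing-to-harvest season (10 Oct–31 May)
with sinusoidal seasonal temperature (winter dip, amplitude 8 °C) around
the published growing-season means for the Hengyang station, AR(1)
day-to-day noise (SD 2 °C, ρ 0.7), Bernoulli-gamma precipitation,
truncated-normal sunshine and jittered vapour pressure and wind. Noise
terms are recentred and precipitation rescaled so the window means equal
the spec means by construction — one season is too short for raw sample
means to stay reliably within the declared 10% envelope. Radiation is
derived from sunshine hours by the Ångström–Prescott relation
(a = 0.25, b = 0.50).

Campaigns sample the engine's own trace at DVS triggers
(0.2, 0.6, 1.0, 1.5, 1.9) — stage dates are therefore weather-adaptive —
with multiplicative lognormal noise (default CV 5%, a measurement-error
choice, not a published value); the first three stages force SAI = 0 so
TPAI = LAI, matching the field protocol in which siliques are absent
before the milky stage.

What the generator does **not** emulate: spatial heterogeneity between
sampling points, instrument-specific biases of optical LAI measurement,
frost or pest damage, nutrient limitation, and real vernalisation-driven
phenology (the thermal-time surrogate with TBASE = 5 °C merely reproduces
the stage calendar). Passing twin experiments therefore demonstrates
internal identifiability of the methods, not field accuracy.

## Numerical choices

- AFGEN tables: piecewise-linear, clamped at both ends; binary-searched.
- Optimizer: scipy `least_squares` (trust-region reflective) on the unit
  cube with relative finite-difference step 0.02 and a 60-evaluation
  budget by default; parameters are clamped into their published bounds at
  entry and the fit cannot leave them.
- Stage-date lookups past the end of a finished run clamp to the final
  state (the crop is mature; its yield no longer changes).
- The partition-constraint transform is exact in floating point to a few
  ulps; the acceptance script reports the mean row sum over 1e5 rows.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give byte-identical weather,
  truths, campaigns and EFAST designs.

## Known limitations

- The engine is a re-implementation of the WOFOST potential-production
  scheme, not a wrapper of an existing distribution; no cross-check
  against an external reference implementation is run offline, and the
  conservation and collapse tests stand in for it.
- Pod area carries no senescence before maturity and pod temperature
  response equals leaf response.
- The TPAI-SPA objective cannot separate SPA from storage mass along the
  product SPA·W_pod using canopy observations alone; the staged yield
  anchoring resolves this in practice but correlated errors in TPAI and
  TWSO observations would re-open it.
- Water-limited mode is deliberately simple (one bucket, Hargreaves
  reference ET) and is not used by the headline analyses.
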