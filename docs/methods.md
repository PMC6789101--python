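# Methods

## Problem and scope

The pipeline quantifies how climate, atmospheric CO₂ and nitrogen
deposition drive changes in ecosystem water-use efficiency (WUE = GPP/ET)
and carbon-use efficiency (CUE = NPP/GPP) across a factorial ensemble of
terrestrial ecosystem model simulations spanning 1901–2010. The factorial
ladder RG1 ⊂ SG1 ⊂ SG2 ⊂ SG3 ⊂ BG1 adds one driver per rung (climate, land
use, CO₂, N deposition), so single-driver impacts are scenario
differences: climate = SG1 − RG1, CO₂ = SG3 − SG2, N deposition =
BG1 − SG3. The combined impact is the all-drivers scenario net of its 1901
value. Carbon-only models have no nitrogen cycle and stop at SG3; a model
may lack a variable outright (a model without evapotranspiration enters
the CUE analysis only). Land-use attribution (SG2 − SG1) is supported by
the generator as an effect knob (default zero) but is not part of the
headline outputs.

## Gridded fields and units

All fields live on a (lat, lon, time) grid with cell-center coordinates,
a boolean land mask, and NaN as the single missing sentinel; any
computation touching a missing value yields missing, never zero, so ocean
cells cannot bias aggregates. Units are normalized on read to a closed
canonical set — gC m⁻² yr⁻¹ for carbon fluxes, kgH₂O m⁻² yr⁻¹ (≡ mm yr⁻¹)
for ET, m² m⁻² for LAI, kg m⁻² and K for the soil variables — using a
365-day year for per-second rates (error < 0.1 %, and the synthetic
pipeline is self-consistent). Normalization is idempotent. Annual time
axes are integer calendar years; monthly LAI uses fractional years
year + (month − ½)/12, with months recovered exactly by rounding. NetCDF
output is CF-style classic format (scipy backend), deterministic for
fixed input, with `_FillValue`/`missing_value` honored.

## Efficiency ratios and aggregation

WUE and CUE are formed per cell with denominator floors — ET < 10
kgH₂O m⁻² yr⁻¹ or GPP < 1 gC m⁻² yr⁻¹ yields missing, never 0 or ∞ —
guarding desert and ice cells; both floors are config-exposed. CUE values
outside [0, 1] (negative-NPP years in some models) are retained, not
clipped, because clipping would bias trend statistics; a QC report counts
them. Spatial reduction weights land cells by cos(latitude), excluding
missing cells from numerator and denominator per time step. For ratio
quantities two aggregation orders exist and differ on heterogeneous
grids; the default is aggregate-then-divide (ratio of area-weighted flux
means), which is robust to near-zero-ET cells, and the mean-of-cell-ratios
alternative is exposed for sensitivity analysis
(`ratio_of_means_vs_mean_of_ratios`). Annual ratios are formed from
annual sums/means; forming them at monthly resolution first would weight
seasons differently and is out of scope.

## Trend statistics

The Mann-Kendall statistic is S = Σ_{i<j} sign(x_j − x_i) with
tie-corrected variance Var(S) = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18 over
tie groups of size t, continuity-corrected normal score
Z = (S ∓ 1)/√Var(S), and a two-sided p-value (α = 0.05 default).
Kendall's tau is reported tie-adjusted (tau-b), matching scipy's
definition, and lies in [−1, 1]; it — not S or Z — is the quantity that
"ranges from −1 to 1". Sen's slope is the median of all pairwise slopes
(x_j − x_i)/(t_j − t_i); duplicate time points are rejected as malformed.
A constant series gives S = 0, p = 1, no trend. Series shorter than 4
(MK) or 10 (TFPW) values are rejected.

### Trend-free pre-whitening

Interannual autocorrelation inflates the MK type-I error (measured here:
~26 % rejection at α = 0.05 for an AR(1) null with ρ = 0.5, n = 110).
TFPW: (1) estimate β by Sen's slope; (2) detrend y_t = x_t − β·t; (3)
estimate the lag-1 autocorrelation r₁ of y; (4) if |r₁| ≥ 1.645/√n (10 %
two-sided normal bound; gate configurable to "always" or "never") remove
the AR(1) component; (5) blend the trend back on the original indices
2..n (the series shortens by one, which enters Var(S)) and apply the MK
test to the blended series. Sen's slope is always reported from the
original series — the slope is a property of the data; whitening only
fixes the inference.

Two calibration choices in step (4) are this package's own. First, the
coefficient actually removed is bias-corrected, r₁c = r₁ + (1 + 3r₁)/n,
because the sample lag-1 autocorrelation of detrended AR(1) noise is
biased low and leaves the series under-whitened. Second, the whitened
residuals are rescaled by 1/(1 − r₁c). Without the rescaling the spurious
Sen slope of an autocorrelated null series — whose sampling standard
deviation scales as √((1+ρ)/(1−ρ)) — is re-blended against residuals
shrunk to √(1−ρ²) of the original noise, and the test statistic behaves
as N(0, 2) at ρ = 0.5: a ~33 % false-positive rate that no gate can fix.
With both refinements the measured type-I error at ρ = 0.5, n = 110 is
6–7 % across seeds, and power for a 1-noise-sd-per-decade trend over
AR(1)(ρ = 0.3) noise is ~100 %. The unscaled variant remains available
(`tfpw_transform(..., scale=False)`). No additional variance correction
(e.g. effective-sample-size inflation of Var(S)) is applied; TFPW is the
sole autocorrelation treatment.

### Change metrics

Percentage change = 100·(Sen slope)·n/mean, with n the period length in
years and the mean taken over the same series; it is exactly linear in
the slope and in 1/mean, and undefined for zero mean. For driver-effect
rows in the summary table the mean in the denominator is the
combined-scenario (BG1/SG3) series mean, so the metric reads "percent of
typical WUE/CUE", and effect series that cross zero do not blow it up.
Percent increase between two years is 100·(x[y₁] − x[y₀])/x[y₀]. Percent
contribution of a driver is 100·mean(effect series)/mean(combined-
scenario series) over the same years and scope, with the BG1 denominator
for carbon–nitrogen models and SG3 for carbon-only models.

## Attribution and dominance

Efficiencies are computed per scenario first and then differenced (the
driver's effect on WUE, not the WUE of flux differences). The dominant
driver at a cell is the argmax over applicable drivers of the absolute
percent contribution computed from per-cell period means (default period
1982–2008); cells where every driver falls below 0.1 percentage points
(config-exposed; 0 allowed) are labeled "none", ties break in the fixed
order climate > co2 > ndep, and signed magnitudes are retained for audit.
Absolute values are used so that strong negative (climate) effects can
dominate. Maps are produced per model and for the multi-model mean of
the per-cell effect and denominator maps, each model contributing its own
maximal scenario; both views are provided because ensemble-mean and
per-model dominance can legitimately differ.

## Evaluation

Modeled WUE from the climate-only scenario (SG1) is compared to a
reference WUE series over 1982–2008 (27 annual values): MAE, mean bias,
and TFPW-MK trends on both series. The MAE is computed on global-mean
series; a per-cell variant is a straightforward extension but the
aggregate comparison is the implemented default. The LAI N-deposition
procedure averages, for each year, the area-weighted monthly mean LAI of
April–October (7 months, equal weights) over land cells with center
latitude strictly north of 25°N (the nitrogen-limited zone; boundary
cells excluded), for the BG1 scenario and for the BG1 − SG3 difference.
It requires a carbon–nitrogen model whose LAI is dynamically estimated;
models with prescribed (satellite-based) LAI are excluded via a
`lai_dynamic` capability flag.

## Synthetic ensemble generator

The generator fabricates what the analysis needs and nothing more: for
scenario s with active driver set D(s), flux v at land cell (i,j) and
year t is

    v_s(i,j,t) = v0(i,j) · (1 + Σ_{d∈D(s)} eff_d[v]·f(t)) · (1 + n_v(i,j,t)),

with f(t) ramping 0→1 over 1901–2010, eff a signed fraction per driver
and variable, and n an AR(1) noise series (stationary initialization,
lag-1 coefficient ρ, innovation sd as a fraction of baseline). Driver
effects are deliberately additive inside one bracket and linear in time
rather than realistic forcing responses: scenario differences of fluxes
are then exactly closed-form, so attribution recovery is testable to
machine precision; interactions enter only through the WUE/CUE ratios and
are second-order. Noise realizations are shared across the scenarios of
one model (per-variable, per-cell seeding), mirroring ensembles driven by
common weather forcing and making scenario differences noise-free up to
the multiplicative factor; an `independent_noise` switch provides the
stress-test configuration. Ra = GPP − NPP (non-negative by 0 < cue0 < 1
and bounded effects), LAI is monthly with a hemisphere-aware unit-mean
sinusoidal seasonal cycle scaled by the annual driver factor, and soil
moisture/temperature are baseline plus an additive climate trend plus
noise. Baseline climatologies are smooth multiplicative spatial patterns
around scalar means (GPP 1200 gC m⁻² yr⁻¹, CUE₀ 0.5, ET 500 kgH₂O m⁻²
yr⁻¹, LAI 3 m² m⁻², ±30 %); the land mask thresholds a smoothed Gaussian
field at the requested land fraction. Effects can be restricted to a
latitude band per driver for spatial-recovery experiments. A JSON
ground-truth ledger of injected effects accompanies every archive, and
identical (spec, seed) inputs yield bit-identical output.

The default archive holds three pseudo-models chosen to span reported
ensemble behaviour: a CO₂-fertilization-dominated C-N model (CO₂ GPP
effect +25 %/span, WUE rise ~20 %), an N-deposition-dominated C-N model
(N-dep GPP +10 %), and a climate-dominated carbon-only model (climate GPP
−12 %, ET +5 %, WUE decline ~−15 %); N-deposition effects elsewhere sit
near the observed few-percent GPP / half-percent ET scale. Noise defaults
are ρ = 0.35 and sd = 2 % of baseline — a realistic interannual
variability for global-mean fluxes. The default grid is 10×20 cells with
55 % land, 1901–2010: large enough for spatial classification statistics,
small enough that the full pipeline runs in seconds. What the generator
does not emulate: real model physics (stomatal conductance, nutrient
down-regulation, hydrology), realistic forcing time courses, spatial
covariance beyond the smooth baselines, or observational error structure
in the reference product (flat base plus iid noise). Passing recovery
tests therefore demonstrates correctness of the differencing, statistics
and classification machinery — not fidelity of any real model's response.

## Numerical choices and degenerate inputs

Missing data propagate as NaN throughout; aggregation drops missing
cells per time step. A constant series is a valid trend-test input
(p = 1). A perfectly linear series has zero-variance residuals; its r₁
is defined as 0 and TFPW is the identity. Duplicate time points and
series below the minimum lengths raise errors rather than guessing.
Dominance ties break deterministically; ocean cells carry label −1 in
the categorical NetCDF with `flag_meanings` "none climate co2 ndep".
All seeds derive from a single run seed via numpy SeedSequence spawning,
so every artifact is reproducible bit-for-bit.

## Known limitations

- The aggregate-then-divide default means global WUE is a flux-weighted
  ratio; regions with high GPP dominate. The alternative order is
  provided but not the default.
- TFPW handles AR(1) serial correlation only; long-memory or seasonal
  structure would require seasonal MK or block-bootstrap methods, which
  are out of scope.
- The reference product stand-in is synthetic; comparisons exercise the
  machinery, not observational skill.
- No regridding: all models in an archive must share one grid.
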