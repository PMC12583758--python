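# Methods

## Scope and model

`livecarbon` estimates greenhouse-gas emissions of a city×year livestock
panel with a cradle-to-market life-cycle accounting scheme and analyses the
resulting emission panel with three spatial/temporal statistics: a Theil
within/between-region decomposition, Tapio decoupling classification
against livestock output value, and conventional plus spatially
conditioned Markov chains of emission types.

### Life-cycle accounting

Seven stages are computed per city and year from head counts `APP_i`
(annual average head of species i), product outputs `Q_T` (t/a), feed
consumption factors `t` (t feed per t product), concentrate grain shares
`q_j`, and per-head energy expenditure:

- feed-grain cultivation: `EFC = Σ_T Q_T·t_T · Σ_j q_j·ef_j1` (t CO2-eq)
- feed transport/processing: `EFT = Σ_T Q_T·t_T · Σ_j q_j·ef_j2` (t CO2-eq)
- enteric fermentation: `EFG = Σ_i APP_i·ef_i1` (kg CH4)
- manure CH4 / N2O: `EFM = Σ_i APP_i·ef_i2`, `EFS = Σ_i APP_i·ef_i3` (kg)
- feeding energy: `EFE = Σ_i APP_i·(cost_ie/price_e)/1000·ef_e
  + Σ_i APP_i·(cost_ic/price_c)·ef_c` (t CO2)
- processing: `EFP = Σ_T Q_T·1000·(MJ_T/e_n)/1000·ef_e` (t CO2)

and the CO2-equivalent total

`ETotal = EFC + EFT + (EFG + EFM)·GWP_CH4/1000 + EFS·GWP_N2O/1000 + EFE + EFP`.

Two unit bridges are fixed by the source units of the coefficients and are
applied nowhere else: electricity expenditure divided by price gives kWh
while the grid factor is t CO2 per MWh (÷1000), and per-head gas factors
are kg while GWP aggregation is in tonnes (÷1000). Internal computation is
always in tonnes; the reporting layer divides by 10^4 ("ten-thousand
tonnes") only when writing output tables.

Two GWP sets are built in: a 100-year horizon (CH4 27, N2O 273) and a
20-year horizon (CH4 81.2, N2O 273). Since 81.2 > 27 and the N2O factor is
unchanged, the 20-year total dominates whenever any CH4 is emitted; this
monotonicity is property-tested.

Coefficient conventions: poultry have no rumen fermentation, so their
enteric CH4 factor is an exact 0 (logged once). Soybean carries a
transport/processing factor but no cultivation factor; its cultivation
term is *absent* (`None`, distinct from 0) and the cultivation stage skips
it with a warning unless a user override supplies a value through the YAML
factor config.

Annualized rates of change are geometric, `(v1/v0)^(1/(y1−y0)) − 1` —
chosen because it is the compounding-consistent definition and is
invariant to rescaling the series. Stage–total association uses Pearson
correlations of the provincial annual series with two-sided p-values from
the t distribution (n−2 df); manure CH4 and N2O are combined into one
CO2-eq manure series for this purpose. Zero-variance series yield NaN
rather than an exception.

### Theil decomposition

The Theil-T (GE(1)) index `T = (1/n) Σ (E_i/μ) ln(E_i/μ)` is decomposed
with emission-share weights `s_g = n_g μ_g/(n μ)` into
`within = Σ_g s_g T_g` and `between = Σ_g s_g ln(μ_g/μ)` — the unique
additive decomposition for this entropy form. Additivity is asserted to
1e-12 on a thousand random instances, and the implementation is checked
against an explicit two-pass loop oracle to 1e-14. The index's true upper
bound is ln n, not 1; nothing here clips it. Contribution percentages are
component/total×100 and undefined (reported as null) under perfect
equality. The economic-development variant runs the same decomposition on
total city output value.

### Tapio decoupling

For each consecutive year pair, `E = (ΔC/C)/(ΔG/G)`. Eight states follow
from the signs of the changes and the band of E, with band boundaries 0.8
and 1.2 belonging to the coupling band (`0.8 ≤ E ≤ 1.2`). For consistent
inputs the sign of ΔC is implied by E and sign(ΔG), so the classifier
conditions on sign(ΔG) and E only; this makes it total over boundary cases
(ΔC = 0 during growth → E = 0 → weak decoupling) and lets it classify
externally quoted triples by their reported elasticity rather than the
ratio of rounded deltas, which can drift across a band edge. ΔG = 0 yields
a sentinel `undefined` state, never an exception.

### Markov chains of emission types

City-year emission values are pooled and cut at empirical quantiles j/K
(K = 4 by default: low, medium-low, medium-high, high). Bins are
lower-closed; typing is rank-based and hence invariant to monotone
transformations. Annual transitions are counted over all cities and
row-normalised by maximum likelihood, `p̂_ij = n_ij/n_i`; never-visited
rows are kept as flagged zero rows. The spatial variant computes each
city's spatial lag — the unweighted mean of its contiguity neighbours'
values (row-standardised binary weights) — bins it with the same pooled
thresholds, and stratifies each transition by the lag class at the origin
year. Stratified counts sum to the conventional counts exactly, which is
asserted on every instance.

Adjacency is supplied as an explicit symmetric edge list rather than
derived from geometry; ring and rook-contiguity lattice builders cover
synthetic use.

## Synthetic data

The generator emulates the statistical shape of a provincial livestock
panel: 18 cities in 5 regions over 2001–2021 by default. Inventories are
city-specific lognormal base levels (sigma 0.35 across cities) × a region
multiplier × `(1+trend)^(year−start)` × mean-one lognormal noise. The
geometric trend form makes the annualized rate of a noise-free series
equal the configured trend exactly, which anchors the rate computation in
tests. Defaults, chosen once to mirror the emulated study conditions:
trend −0.0118/a for every species; one dominant region (multiplier 2.0,
"Southern") with the others spanning 0.6–1.2; noise coefficient of
variation 0.08; per-city output value growing 9%/a (sd 4%) with recession
draws (−5% mean) in 2006, 2009, 2014 and 2020; head-count medians of
plausible provincial magnitude (e.g. 2×10^6 pigs, 2×10^7 poultry per
city). Product outputs are strictly proportional to inventories through
per-head yields, and per-head energy expenditures are constants, so the
generated panels are smoother than real yearbook data: no reporting
breaks, no species-specific shocks, no measurement error in the economic
series. Passing tests therefore demonstrate correctness of the estimators
and the pipeline's plumbing, not calibration to any real province.

A separate generator simulates independent realisations of a known
K-state Markov chain from uniform initial states; it is the recovery
oracle for the transition-matrix estimators (max row-wise L1 error < 0.05
at 100 units × 300 years) and, run on a ring with neighbour-blind
dynamics, for the null behaviour of the spatial stratification.

## Numerical choices and degenerate inputs

- Missing panel cells are filled per city series by inverse-distance
  weighting of the two nearest observations (linear interpolation in the
  year index); boundary gaps copy the nearest observation; imputed cells
  are flagged and already-observed cells are left bit-identical.
  All-missing series raise. Imputation is idempotent.
- CSV reading uses round-trip float parsing so write→read→write is
  bit-stable.
- Quantile thresholds use the default linear interpolation of the
  empirical quantile function; a value exactly on a cut belongs to the
  upper bin (lower-closed bins). Requesting more bins than distinct values
  raises.
- Theil requires strictly positive values (domain error otherwise);
  decoupling requires positive base-year values.
- Stage operations are homogeneous of degree one in inventories/outputs
  (property-tested), so provincial totals are plain sums.

## Problem sizes

Default test and report runs use the 18×21 panel (378 records), 1000
random instances for the Theil identities, and 100×300 simulated chains
for Markov recovery; the full suite runs in a few seconds on one core.

## Limitations

- Emission factors are constant over space and time; no region- or
  year-specific factor sets.
- No roughage cultivation, land-use change, or sequestration terms.
- The feed factors and grain shares are user data with synthetic defaults;
  results scale linearly with them.
- The spatial weight construction is binary contiguity with equal
  weights; distance- or flow-based weights are out of scope.
- No forecasting: the Markov matrices describe observed transitions only.
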