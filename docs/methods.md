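# Methods

This note documents the model implemented by `smallholder`: its
structure, assumptions, parameterization, numerical conventions, what
the synthetic inputs do and do not emulate, and known limitations.

## Entities and scales

Space is a regular row-major grid of 50 m × 50 m cells (0.25 ha), default
100 × 100 (25 km²), 4-neighborhood contiguity, no wrap-around. Five
nested spatial units exist: *cell* → *field* (contiguous same-crop,
same-age cells of one household) → *household area* → *patch*
(contiguous same-crop, similar-age cells regardless of ownership,
derived on demand for habitat analyses) → *landscape*. Time advances in
annual steps; the standard experiment is 50 years × 20 replicates.

Households carry wealth (a signed balance: positive part is `h_wealth`,
negative part `h_debts`), two crop-specific inefficiencies in [0, 1], a
fixed set of fields, a fixed social network, and a full annual cost/
revenue ledger. Cells carry land use (forest / oil palm / rubber), stand
age, ownership, production, input, capital-stock and carbon layers.

## Annual schedule

Each year executes, in this order: (1) learning (if enabled),
(2) Consumption I, (3) the land-use decision and its implementation,
(4) production, costs and net cash flow, (5) Consumption II, (6) the
wealth/debt/freeze update, (7) the carbon update, (8) recording of
observables, (9) the price update for the next year and stand aging.
Decisions therefore always use the current year's prices, and a
(re)planted field stands at age 0 — producing nothing and holding no
carbon — in its establishment year. A regression test pins this
sequence.

## The household economy

**Potential yields** are piecewise-linear profiles of stand age
(t/ha/yr): oil palm is immature to age 3, rises to a 22 t FFB/ha plateau
at age 9, declines from age 18, and must be replaced at 25; rubber is
immature to age 6, holds a 1.8 t/ha plateau from age 12 to 30, declines
to 0.4 t/ha at 40, and must be replaced at 40. The late-age declines are
what force replanting waves.

**Costs** per hectare and year: labor (hours × wage) and technical
input (kg × unit price) follow the yield profile — immature stands need
50 % of the mature schedule, producing stands scale between that floor
and 100 % in proportion to `Y(a)/Y_peak`, reflecting
harvest-proportional effort; land rent is 48 USD/ha; capital fixed at
establishment depreciates linearly to zero over the stand's maximum age
and is charged interest at 10 %/yr; establishment costs 1200 (oil palm)
and 1000 (rubber) USD/ha in the planting year. Mature annual input
costs total 1200 USD/ha for oil palm and 600 USD/ha for rubber. These
schedules are calibration stand-ins: they were chosen, once, so that the
default parameter set jointly reproduces the reference dynamics (see
*Calibration* below), and every value is exposed in `CropParams`.

**Decision rule.** For each field the household evaluates *keep*,
*replant same crop* and *convert* by expected NPV over a 10-year horizon
at a 10 % discount rate, projecting constant prices and constant own
inefficiency ("no anticipated learning"), including forced replacement
of any stand that would exceed its maximum age inside the projection.
Desired changes are admitted greedily in descending NPV-gain per USD of
establishment cost (ties by lower field id) while post-Consumption-I
wealth lasts; voluntary investments are never debt-financed, but forced
replacement at maximum age is unavoidable and may create debt, falling
back to the cheaper replacement option when the NPV-best one is
unaffordable.

**Consumption and survival.** Consumption I = 300 USD subsistence +
5 % of positive wealth, deducted before the decision; Consumption II =
20 % of positive net cash flow, deducted after production. The balance
accrues net cash flow plus (configurable, default zero) external income
minus Consumption II. A household whose balance stays negative for 20
consecutive years freezes: its fields stop aging and producing, and it
is excluded from every subsequent output metric. At equilibrium the
consumption rule makes mean consumption track mean net cash flow, which
is what links the welfare metrics to the production economy.

## Learning and social networks

Networks are built once at initialization from shortest-path road
distances between home bases (50 m per road-cell step between the two
access road cells). Pairs within a 5000 m cap are linked — all of them
in deterministic mode, or independently with probability
`exp(−d/1500 m)` in the (default for learning scenarios) stochastic
mode. Each year a household cultivating crop *c* whose inefficiency
exceeds the current mean of its non-frozen neighbours moves down by
`α (e_c − mean)` with α = 0.25/yr; inefficiencies never increase, and
all updates within a year use the previous year's values
(simultaneous update, so the result is order-independent). The mean is
unweighted over connected, non-frozen neighbours.

## Carbon

Plantation cells hold `C_max (1 − e^{−k a})` t C/ha with
`C_max = 40, k = 0.18` (oil palm) and `C_max = 55, k = 0.12` (rubber);
forest cells hold a constant 150 t C/ha. Above- and below-ground
vegetation carbon are folded into the single stock. Conversion and
replanting reset the stock to zero with the age, which is why frequent
land-use switching depresses landscape carbon. Reported agricultural
carbon is the mean stock per hectare over the agricultural cells of
active households; per-crop "contributions" divide by the whole
agricultural area so the two crops sum to the total.

## Prices

Prices are landscape-wide and exogenous: USD/t dry rubber and USD/t
oil-palm fresh fruit bunches (FFB). Constant mode defaults to the 2012
farm-gate reference values 1100/90 USD/t. The bundled
`prices_historical_synthetic.csv` is a **synthetic** 50-year series
(not observed data): rubber starts near the reference level, declines to
a trough of ~630 USD/t around year 39–40 and recovers, while FFB prices
drift mildly upward around 75–110 USD/t — the qualitative pattern needed
for the fluctuating-price scenarios. The random-walk mode multiplies
prices by `exp(ε), ε ~ N(0, σ²)`, keeping them positive and making the
households' "no change" forecast unbiased on the log scale.

## Synthetic landscape generation

Roads form a rectilinear lattice (spacing 20 cells, centred); home bases
are sampled uniformly among road-adjacent cells; household target areas
are drawn from a normal distribution (mean 50 cells = 12.5 ha, SD 15)
and rescaled so agriculture covers ~50 % of the grid; fields of ~12
cells (~3 ha) are grown around each home base by seeded region-growing
over free cells, with truncated fields compensated by additional smaller
ones. Fields are assigned oil palm or rubber by balancing cell counts to
a 50/50 initial mix, with per-field ages uniform on 1–20 (oil palm) and
1–25 (rubber) to avoid artificial age synchrony at the start. Initial
wealth is drawn from a lognormal (median 2000 USD, σ = 0.8 log-USD) and
rank-matched to household area, so larger holders start wealthier.
Inefficiencies, in the heterogeneous scenarios, are independent
per-crop draws from a Gamma(shape 2, scale 0.3) resampled into [0, 1]
(resampling rather than clipping preserves the distribution's shape).

What this generator does **not** emulate: real road topology, rivers and
terrain, villages, spatial autocorrelation of soil or management
quality, correlated crop skills within a household, or observed field
geometries. Results on synthetic landscapes demonstrate the model's
mechanisms — relative profitability, capital constraints, selection and
learning — not predictions for any actual landscape.

## Randomness and reproducibility

All stochastic elements draw from named, independently spawned RNG
streams (landscape, wealth, inefficiency, network, prices, tie-breaks),
so switching one element on or off leaves the others' draws untouched.
Replicate *r* of a scenario is seeded `seed + r` and regenerates the
entire landscape, so cross-replicate SD bands reflect all stochastic
inputs. Reruns under a fixed seed are bit-identical.

## Calibration

The cost schedules, consumption split, freeze period, and inefficiency
distribution are not observable from first principles here; they were
calibrated **jointly and once** so that the default parameter set
reproduces the reference emergent dynamics at the 2012 prices:

- rubber's expected NPV strictly dominates oil palm's for a bare field
  at every horizon 1–20 (this fixes oil palm's mature input cost at
  1200 USD/ha — with equal peak revenues of ~1980 USD/ha for both crops,
  a cheaper oil palm would win at intermediate horizons);
- full conversion to rubber in ~20 years (15–25), with agricultural
  carbon in the 35–40 t C/ha band during the mixed phase and a
  >45 t C/ha peak after conversion;
- mean consumption more than doubling over the transition;
- a ≥50 % consumption penalty when heterogeneous inefficiencies are
  enabled (this constrains the gamma scale of 0.3, the 300 USD
  subsistence, the 0.20 profit-consumption rate, and the 20-year freeze
  period: with a short freeze period, inefficient households exit the
  population so quickly that survivor selection caps the penalty near
  35 %).

The calibrated defaults were verified on an independent seed batch
before being frozen and are not tuned per run.

## Numerical choices and edge cases

- NPV projections and realized cash flows share one cash-flow
  primitive; a brute-force discounted-sum oracle in the test suite
  checks them to 1e−9 relative over all crops, ages and horizons.
- Ties in the greedy investment ordering break on lower field id;
  all iteration orders over households and fields are fixed, making
  runs deterministic given the seed.
- Zero active agricultural cells (everyone frozen) yields missing
  metric values rather than zeros; a yield gap with zero total
  potential (only immature stands) is likewise missing.
- A road spacing larger than the grid degenerates to a single central
  cross (with a warning); a blocked field-growth front truncates the
  field and the allocator compensates with additional fields.
- The gamma resampling loop has no iteration cap; for the default
  parameters the acceptance probability is ≈0.95 per draw.

## Limitations

Large company plantations, land expansion and markets, demography,
labor markets, risk aversion, soil carbon, hydrology and biodiversity
are out of scope. Oil palm and rubber are the only crops; fallow is not
an option. Prices are exogenous and spatially uniform; there are no
direct neighborhood effects on conversion (neighbours matter only
through learning). The freeze rule is absorbing — frozen households
never re-enter, and their fields remain as static landscape elements
excluded from metrics rather than reverting to forest.
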