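# Methods

## The model

Tree mortality over a remeasurement interval is treated as a binary
outcome per tree-interval record (1 = alive at the interval's end,
0 = died during it). The model is a conditional inference tree (CTREE):
recursive binary partitioning in which both the choice of split variable
and the decision to stop are made by permutation-test p-values rather than
by impurity search. This separates *variable selection* from *split-point
search*, which removes the bias of exhaustive-search trees toward
covariates with many distinct values, and makes the p-value threshold the
tree's only pruning device.

### Split test

At a node holding records `i = 1..n`, each candidate covariate `x` is
transformed to scores `g(x_i)` — the observed values for ordered
covariates (mid-ranks optionally), a one-hot indicator matrix for nominal
covariates — and tested against the death indicator `h(y_i)` through the
linear statistic

    T = Σ_i w_i g(x_i) h(y_i).

Under the null of no association, conditioning on the observed data and
permuting `h` against `g` gives closed-form moments:

    μ  = (Σ w g) · E(h)
    Σ_T = V(h) · [ w./(w.−1) Σ w g gᵀ − 1/(w.−1) (Σ w g)(Σ w g)ᵀ ]

with `E(h)`, `V(h)` the weighted response mean and variance and `w.` the
total weight. The default test statistic is the quadratic form
`c = (T−μ)ᵀ Σ_T⁺ (T−μ)` referred to a chi-squared distribution with
`rank(Σ_T)` degrees of freedom (Moore–Penrose inverse); a maximum-type
statistic (largest standardised coordinate, normal reference with a
coordinate-count Bonferroni correction) is available as an option. The
moment formulas are verified in the test suite against exhaustive
enumeration of all `n!` permutations for n ≤ 7, to 1e-10.

Each covariate's raw p-value is multiplied by the number of candidate
covariates (Bonferroni); the node splits on the covariate with the
smallest adjusted p-value if it is below `alpha`, and becomes terminal
otherwise. Ties in adjusted p are broken by the larger test statistic,
then by schema order, so fits are deterministic and row-order invariant.

### Split-point search

For an ordered covariate the threshold maximises the standardised
two-sample statistic `|T_cut − μ_cut| / sd_cut` over all cutpoints between
adjacent distinct observed values, subject to both children holding at
least `min_bucket` records; the returned threshold is the midpoint of the
straddling observed values. For a nominal covariate the binary level
subset maximising the same statistic is found exhaustively when the node
shows at most `nominal_exhaustive_max_levels` levels (default 10, i.e. up
to 511 subsets), and otherwise by ordering levels by mean response and
scanning them as an ordered variable — a reduction that is exact for a
binary response, and necessary for the 28-level species covariate
(2²⁷ subsets are infeasible).

### Terminal nodes and prediction

Terminal nodes store integer record and death counts; the raw mortality
proportion is their exact ratio. Because remeasurement intervals mix 3-
and 5-year lengths, a node additionally stores an interval-standardised
five-year rate: within the node, the raw proportion per interval length is
converted by compound survival,

    P_m5 = 1 − (1 − P_mΔ)^(5/Δ),

and pooled count-weighted. `predict` routes records to terminals by the
stored splits and returns that five-year rate. There are no surrogate
splits: covariates are complete by construction after QC, and a missing
value at prediction is an error. A nominal level unseen in training is
routed to the child with more training records and logged.

### Control parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | adjusted-p threshold to split |
| `test_stat` | quadratic | chi-squared quadratic form (or `maximum`) |
| `min_split` | 20 | smallest node eligible for splitting |
| `min_bucket` | 7 | smallest admissible child |
| `max_depth` | none | optional depth cap |
| `nominal_exhaustive_max_levels` | 10 | exhaustive subset-search cap |
| `score` | identity | ordered-covariate scores (or `rank`) |

The `min_split` default of 20 mirrors the 20-record floor used for grouped
rates. Identity scores are the default because thresholds are then
expressed in the covariate's own units; rank scores make the fitted
partition invariant under strictly monotone covariate transforms.

## Covariates

Basal area is `π (DBH/2)²` (cm²). ΔBA is the annual BA increment between
consecutive measurements; apparent shrinkage (negative ΔBA) is retained
and only an upper outlier threshold is applied. The threshold is a
configuration value in cm² yr⁻¹ with default 20, chosen because the
source material for this covariate set prints the rule in a unit (cm yr⁻¹)
inconsistent with the covariate's own definition and with the magnitudes
at which trees actually grow; a hard-coded literal value would silently
empty any realistic dataset.

BAL sums the basal area of strictly larger plot trees (a tree is not its
own competitor, and equal-size ties contribute nothing by default; an
inclusive-ties mode exists). ERD divides observed stem density by the
self-thinning maximum `N_max = α (DBH/DBH_r)^{−β}` evaluated at the
quadratic-mean DBH of live stems at the interval's start — the quadratic
mean is the standard stand-density convention. The defaults α = 500
stems ha⁻¹ at DBH_r = 20 cm and β = 1.605 (the classical self-thinning
exponent) are configuration values, as is everything entering `N_max`; a
single self-thinning line is used regardless of species composition.

GDD uses the monthly approximation of the JABOWA family of gap models with
a base of 4.4 °C for all species and calendar-true (leap-aware) month
lengths. Annual GDD and precipitation are averaged over the interval
window `(t_prev, t_curr]` — the interval ends at, and includes, the
remeasurement year; this convention is fixed and documented because
"between previous and current measurements" admits either endpoint.
Slope and solar radiation are consumed as per-plot attributes; computing
them from elevation models is out of scope.

## Response construction

Status histories are recoded to one record per consecutive measurement
pair that starts alive; the pair where a tree first appears dead yields
the single death record and later records are dropped. Trees never
observed alive are skipped and logged. Grouped five-year rates convert
each interval length separately before count-weighted pooling, and groups
under 20 records are eliminated. The tree is fitted on record-level binary
outcomes (terminal nodes then report death proportions), while grouped
five-year rates serve for observed-vs-predicted evaluation; a binary
outcome cannot be fractionally converted, so standardisation happens at
the node/group level, never per record.

The default evaluation grouping is species × quartile bins of ΔBA,
BAL×ERD, GDD and PCP. This cross is appropriate for inventory-scale data
(tens of thousands of records); for held-out folds of a few thousand
records it leaves almost no group above the 20-record floor, so the
grouping is pluggable and the bundled studies use species × GDD quartiles.

## Synthetic inventories

The generator emulates the structure of a provincial PSP network: 400 m²
plots remeasured every 3 or 5 years over 4 occasions, ~25 trees per plot
tallied above 5.1 cm DBH, four nominal age classes, and a species pool of
the eight most frequent codes of the emulated inventory weighted by their
observation counts. Plot climate is a cool-maritime monthly temperature
profile shifted so each plot hits a target annual GDD drawn from
N(1500, 150) degree-days, with N(0, 0.25 °C) year effects so interval
averaging is exercised; annual precipitation targets are N(1100, 130) mm.
Terrain is slope |N(10, 8)| % and insolation N(10000, 1500) Wh m⁻².
Growth adds annual BA increments N(8, 3) cm² yr⁻¹ suppressed by
`exp(−1.2 · ERD)`, floored at zero. These distributions are stand-ins for
an unknown joint covariate distribution and are all configuration-exposed.

Mortality is planted: a `HazardSpec` maps each record's covariate vector
to a five-year death probability (ordered first-match-wins rules over a
baseline, scaled by species multipliers, clipped to [0, 1]), which is
converted to the record's interval length by the inverse of the
five-year standardisation — generator and estimator are consistent by
construction. Each plot draws from a generator seeded with
`(seed, plot index)`, so any plot's data are reproducible independently of
how many plots are generated.

What the generator does *not* emulate: spatial tree coordinates, ingrowth,
fire/insect/windthrow/harvest events, measurement error, spatial
autocorrelation between plots, or species-dependent growth. Passing tests
therefore demonstrate that the pipeline recovers a known law from data
with this structure — not that any particular fitted tree on real
inventory data is correct.

## Validation studies and problem sizes

The bundled recovery study plants a four-region law — conifers
(FB, SB, SR, SW) vs hardwoods crossed with GDD ≤/> 1500, five-year rates
0.03 / 0.10 / 0.12 / 0.25 — on 400 plots × ~25 trees × 4 measurements
(~22,000 records after QC). The fit uses `alpha = 0.001`,
`min_split = 400`, `min_bucket = 200`: a stricter evidence bar and larger
node floors than the defaults, because the study's target is parameter
recovery — terminal-rate estimates should be dominated by region means,
not by occasional noise splits whose children carry few records. The
planted contrasts were chosen so every region boundary carries a linear-
statistic signal far above this bar at the study's sample size. Held-out
agreement uses pooled out-of-fold predictions (each record predicted by
the tree fitted without its plot's fold) grouped by species × GDD
quartiles with the 20-record floor, compared count-weighted.

Type-I error control is checked with 1,000 null simulations (n = 500,
four numeric covariates and an 8-level nominal one, Bernoulli(0.1)
response): the fraction of runs producing any split must not exceed
0.05 + 3 Monte-Carlo standard errors. Split recovery uses 100 replicates
of a planted 0.05-vs-0.15 step at GDD 1500 (n = 10,000): the variable must
be recovered in ≥ 99 replicates and thresholds must concentrate near the
boundary (within half the covariate's standard deviation; the measured
mean absolute error, reported by the acceptance script, is about one
degree-day — the boundary itself cannot be localised to the resolution of
single observation spacings at this sample size).

## Numerical notes and limitations

- Covariance rank for the chi-squared reference is computed from the
  eigenvalue spectrum with a spectral tolerance; a zero-rank covariance
  (constant response or covariate) yields p = 1 and a degenerate node.
- Split search only considers cuts between distinct observed values;
  thresholds are midpoints, so refitting on data shifted by less than the
  local spacing returns the identical partition.
- p-values are asymptotic (chi-squared / normal); no Monte-Carlo
  resampling p-values are provided. At node sizes below a few dozen
  records the asymptotic reference is approximate — the `min_split` floor
  keeps tests in the regime where it is adequate.
- The tree has no surrogate splits, no ensembling, and no cost-complexity
  pruning; stopping is entirely p-value driven.
- Five-year standardisation assumes a constant annualised hazard within an
  interval; there is no competing-risks or interval-censoring machinery.
- Plot-level fold assignment is the default to prevent a tree's earlier
  interval from training the fold holding out its later interval;
  record-level assignment is available for literal random partitioning.
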