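# Methods

## Scope and data model

The package analyses constant-temperature experiments on seed germination
and dark (heterotrophic) seedling growth.  Its inputs are two tidy tables:
per-seedling axis lengths over time (`elongation.csv`: accession,
seedling_id, axis, temp_set_c, temp_actual_c, time_h, length_mm) and
per-replicate cumulative germination counts (`germination.csv`: accession,
replicate, temp_set_c, time_h, germinated, total).  All lengths are mm,
times hours, temperatures °C, and analyses use the *realised* chamber
temperatures (5.0, 9.6, 14.3, 19.2, 25.0, 30.0, 34.2, 40.0 °C), not the set
points.  No images are handled; the package starts from measured lengths.

## Elongation kinetics (Schnute model)

Each seedling axis is fitted independently — no pooling or hierarchical
shrinkage — by the general (a ≠ 0, b ≠ 0) solution of Schnute's model with
the reference times τ1, τ2 fixed at the first and last observation, leaving
(a, b, y1, y2) free.  Fixing τ removes the worst ill-conditioning; the
fitted y1, y2 are then the curve's values at the window ends.  `|b| < 1e-6`
switches to the analytic b → 0 (Gompertz-type) limit and `|a| < 1e-9` to the
linear-in-t limit, so the parameter space has no numerical holes.

Fitting is bounded least squares (`scipy.optimize.least_squares`, tolerances
1e-13) from a deterministic 4 × 4 multi-start grid a ∈ {0.005, 0.02, 0.05,
0.1} × b ∈ {−1, 0.25, 0.5, 1.5}; the best-RSS start wins, ties broken by
smaller |b|.  Bounds: a ∈ [1e-4, 2] h⁻¹, b ∈ [−5, 5], y1, y2 ∈ [0.05, 4·max
observed + 1] mm.  The 0.05 mm floor on y1 is the measurement resolution:
allowing the fitted start length to collapse toward zero lets the relative
rate RER = AER/y blow up on noisy series.  Fewer than 5 observations is a
refusal; an exactly constant series or a window with no converged start
returns a flagged failure record, never an exception — at 40 °C most series
are short (early mortality) and are expected to fail, and 40 °C fits are in
any case excluded from all rate-versus-temperature analyses.

Rates are extracted analytically.  The candidate times for the maximum
elongation rate are the window ends plus every bracketed interior root of
the analytic second derivative (sign scan on a 512-point grid polished by
Brent's method); the argmax of AER over the candidates gives t*, MER =
AER(t*), RER_max = MER/y(t*).  `inflection_found` is true only for an
interior t*.  For 0 < b < 1 with an interior inflection RER_max = a/(1−b)
exactly; this identity is verified to 1e-9 in the tests and acceptance
script.  RER_max is defined as RER *at the time of maximum AER*, not the
supremum of RER over the window (which for these curves sits at the window
start and is dominated by the division by the smallest length).

Growth plateaus are confirmed by the earliest run of ≥ 3 consecutive
observations whose pairwise relative differences are ≤ `rel_tol` (default
0.02); the reported final length is the last observed length.  Shoot:root
ratios divide the hypocotyl by the radicle length in the last image and are
flagged undefined at radicle length 0.  Final length versus temperature is
an ordinary quadratic OLS; curvature within 1e-9 of zero (at the data's
scale) is reported as non-concave with an undefined vertex.

## Germination kinetics (non-rectangular hyperbola)

Cumulative germination is modelled in percent (0–100) as the lower root of
θG² − (αt′ + Gmax)G + αt′Gmax = 0 with t′ = max(t − tc, 0), evaluated in the
cancellation-free form G = 2αt′Gmax / (A + sqrt(A² − 4θαt′Gmax)),
A = αt′ + Gmax.  The curve rises with initial slope α after the lag tc and
saturates at Gmax; θ interpolates between the rectangular hyperbola (θ → 0)
and the ramp min(αt′, Gmax) (θ → 1).  Counts are converted to percent with
each replicate's own seed total.

Bounds: Gmax ∈ (0, 100], α ∈ (0, 50] %·h⁻¹, tc ∈ [0, max t], θ ∈ [1e-3,
0.999].  The deterministic multi-start grid combines a crude slope estimate
(× 0.5, 1, 2), tc ∈ {0, last all-zero time} and θ ∈ {0.3, 0.7, 0.95}.  A
replicate in which no seed germinates is recorded as a sentinel (Gmax = 0,
no kinetic parameters).  Replicate means per accession × temperature feed
the multivariate stage; cells whose kinetics are undefined (dead cells) are
imputed α = 0 and tc = the follow-up period (a censored lag), with an audit
log of every imputed cell.

## Beta thermal responses and curve comparison

Rates versus temperature are fitted by the Beta response function with the
cardinals fixed at Tmin = 0 °C and Tmax = 40 °C, free (MR, Topt, δ), bounded
least squares multi-started on Topt ∈ {20, 25, 30, 35}.  Elongation
responses are fitted to the *pooled individual* RER_max points (up to 30
seedlings per temperature), not temperature means; germination-rate
responses are fitted to the replicate-mean α values.  Cells at exactly
T = Tmax are excluded from germination-rate fits: the model is identically
zero there, so they cannot inform the parameters.

Two accessions' responses are compared by the extra-sum-of-squares F-test
on nested fits: one pooled curve (3 parameters) against one curve per
accession (6), F = ((RSS_pooled − RSS_sep)/3)/(RSS_sep/(n − 6)).  Because
seedling variability is multiplicative, residual variance grows with the
mean rate across temperatures, and the unweighted statistic is markedly
anticonservative (measured type-I ≈ 0.07 at nominal 0.01 under the
generator's own noise).  Residuals are therefore weighted by the reciprocal
within-temperature standard deviation of the *combined* sample — the same
weights for the pooled and the separate fits, preserving nesting.  Under
this scheme the measured type-I error is 1.0% at nominal 1% (500 same-truth
simulations) with power 100% for a 40% difference in MR at 30 seedlings per
temperature.  The relation between germination and elongation rates is a
per-axis OLS of mean RER_max on mean α over matched accession × temperature
cells.

## Multivariate stage

Trait matrices are built parameter-major, temperature-minor: germination
(Gmax_T, α_T, tc_T at 8 temperatures → 24 columns) and growth (radicle and
hypocotyl RER_max at the 7 sub-lethal temperatures → 14 columns).  PCA is an
eigendecomposition of the correlation matrix (columns standardized with
ddof = 1), so eigenvalues sum to the column count and, with 7 accessions, at
most 6 are nonzero.  Variable contributions are 100 × squared unit-norm
eigenvector entries, summing to 100% per component; eigenvector signs are
fixed by making each vector's largest-magnitude entry positive.

HCPC is Ward linkage on Euclidean distances between accession scores in the
leading components — by default the smallest number reaching 90% cumulative
variance, configurable — with the tree cut into k = 3 groups (labels
renumbered by first appearance, so the partition is invariant to row
order).  The consolidation/k-means refinement of some HCPC variants is not
implemented.  A Newick export of the tree is provided.

## Synthetic experiments

The generator reproduces the reference design: 8 treatments (set points 5 to
40 °C with the realised temperatures, RH and sampling schedules above; one
picture at transfer plus one per interval gives 15 pictures everywhere
except 40 °C), 30 seedlings × 2 axes per accession × treatment, 4
germination replicates of 50 seeds.  Germination is scored twice per
photographic interval (at least every 4 h) — counting is cheaper than
photography, and warm-temperature kinetics (lags near 15 h) would otherwise
be unresolved.

Per accession the truth comprises Beta curves for radicle RER, hypocotyl RER
and germination α; a broad Beta germinability curve spanning −2 to 43 °C (so
some seeds germinate at 40 °C, where seedlings die — the germination trait
matrix keeps all 8 temperatures); a thermal-lag rule tc(T) = lag/T (a fixed
heat sum, °C·h); an NRH curvature θ; final-length parabolas per axis with
vertices in 15–19 °C and a hypocotyl:radicle ceiling ratio < 1; and noise:
lognormal seedling RER variability (CV 25% radicle, 12% hypocotyl —
radicles are the more variable axis), lognormal final-length variability
(CV 10%), Gaussian measurement noise σ = 0.3 mm, and 0.8 probability of
death before the second picture at 40 °C.  The default seven accessions
span three archetypes — four *sativa*-type varieties, two landraces, one
*falcata*-type cool-optimum accession — with elongation maxima of
0.042–0.059 mm·h⁻¹·mm⁻¹ at optima of 27–35 °C.

Trajectories are Schnute curves with the drawn RER imposed at the
inflection (a = RER·(1−b); b = 0.6 radicle, 0.35 hypocotyl) and the
accession's final length imposed as the *asymptote*; the length reached by
the end of the window is whatever the rate allows, which keeps cold
treatments slow and short, as they should be.  Germination times are drawn
per seed by inverse-transform sampling of the NRH curve treated as a CDF
scaled by Gmax/100 (the inverse is closed-form), so cumulative counts are
monotone by construction.  All randomness flows from a single seed through
`numpy.random.SeedSequence` spawns; identical configurations give
byte-identical CSVs.

Treatment accounting: growing degree-days are max(T − base, 0) × period/24
rounded to the nearest integer (base 0 °C), and vapour-pressure deficit uses
the Tetens saturation pressure es(T) = 0.6108·exp(17.27 T/(T + 237.3)) kPa
times (1 − RH/100).

### What the generator does and does not emulate

It reproduces the design's structure, the multiplicative within-accession
variability, axis asymmetry (S:R < 1, radicle noisier), 40 °C lethality and
seeded determinism.  It does not emulate chamber temperature fluctuations,
seed dormancy or death during germination, spatial/box effects, or
non-Gaussian measurement error from image analysis.  Two known departures
from real data: synthetic trajectories approach their ceiling more gradually
than real seedlings' determinate growth stop, so the 3-picture/2% plateau
rule confirms in only a minority of synthetic series (the analysis driver
reports the fraction and uses last-image lengths for the final-length
parabolas); and fitted per-seedling RER_max inherits a right tail from the
multiplicative noise, so pooled Beta MR estimates run some 10–20% above
truth at warm temperatures.  Passing tests therefore demonstrate correct
recovery under this stylised noise model, not under every pathology of real
imaging data.

## Numerical choices and defaults

* plateau `rel_tol` 0.02 over 3 consecutive images (no published tolerance
  exists; 2% of a near-final length is about the measurement noise).
* comparison α = 0.01; HCPC k = 3; retained components = 90% cumulative
  variance rule.
* least-squares tolerances 1e-13, max 400 function evaluations per start;
  all multi-start grids deterministic, so every fit is reproducible without
  a seed.
* report rounding: rates 3 decimals, temperatures 1 decimal.
* degenerate inputs are contracts, not crashes: constant series → failure
  record; all-zero germination → Gmax = 0 sentinel; all-zero rates → flagged
  Beta failure; radicle length 0 → undefined S:R; zero-variance PCA column
  and unresolvable missing cells → errors naming the column/cell.

## Problem sizes used in tests and the acceptance script

Noiseless round trips use single series (15–20 points).  Monte-Carlo checks
use 200 replicates (Schnute noisy recovery, binomial Gmax recovery, Topt
recovery at 30 seedlings × 7 temperatures × CV 25%, F-test power), 500
same-truth runs for type-I calibration, 100 runs for HCPC archetype
recovery, and 1000 random draws for the closed-form identities.  The full
default experiment (3360 trajectories, 224 germination replicates) is fitted
end-to-end by the analysis drivers; the test suite exercises the same
pipeline at 3 accessions × 4 seedlings.  The acceptance script runs in
about 90 s on one CPU.

## Known limitations

Seedlings are fitted independently; there is no mixed-effects pooling, no
dormancy or hydrotime/thermal-time population modelling, and no piecewise
(bilinear) cardinal models.  The Beta cardinals are fixed at 0/40 °C; if a
process kept measurable rates at 40 °C the fit would be misspecified there
(the generator's germination truth intentionally has this property, and the
fitted curves absorb it).  PCA on 7 accessions has at most 6 informative
components; clustering stability below ~3 accessions per group is limited.
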