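# Methods

This note documents the models implemented in `spreadca`, the choices made
where the methods literature leaves the design open, what the synthetic
data generator does and does not emulate, and the known limits of the
calibration procedure. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Occurrence preparation

Presence records carry coordinates, a coordinate uncertainty (m), and a
label. Cleaning applies two filters: records with uncertainty above
`max_uncertainty` (default 100 m) are dropped, and the remainder is
spatially thinned to a minimum spacing (`min_interpoint`, default 30 km).
The thinning algorithm is a greedy scan in input order — a point is kept
iff it is far enough from every already-kept point — chosen because it is
deterministic and idempotent; thinning algorithms differ in which points
survive but not in the spacing guarantee, which is the property the
downstream model relies on.

Pseudo-absences are placed by rejection sampling uniformly over a region
mask, each at least `pa_min_dist` (default 110 km, roughly one degree)
from every presence and every other pseudo-absence, with an attempt budget
of `1000 × n` before a capacity error reports the achieved count. Distances
are haversine when the coordinate tag is geographic and Euclidean on
projected frames.

Residual spatial autocorrelation is checked with Moran's I using
inverse-distance, row-standardized weights — the most common default; the
choice is recorded in the result object — with a two-sided permutation
test centered on the null expectation E[I] = −1/(n−1).

## Suitability modelling

Covariate reduction runs in two phases. Phase 1: while any remaining pair
has |Pearson r| above 0.8, the member of the most-correlated pair with the
higher variance inflation factor is dropped. Phase 2: the highest-VIF
covariate is dropped until every VIF is below 4 — the loop terminates only
on that condition. VIF is computed from the R² of regressing each
covariate on the rest; a perfectly predictable column gets VIF = ∞, and
ties (including ties at ∞) break deterministically toward the
lexicographically later column name so selection is reproducible.

The learner is a random-forest classifier treated as a supplied component
with a fixed contract: per-point presence probability and node-impurity
importances. Data are split 7:3, stratified by label. Partial dependence
is the mean prediction over the training rows with one variable clamped to
a grid.

Evaluation metrics:

* **Continuous Boyce index.** The suitability range is covered by 101
  moving windows of width 1/10 of the range (the classical formulation;
  both knobs are arguments). Each window's predicted-to-expected ratio is
  the fraction of presences in the window over the fraction of background
  points; windows with zero background are skipped, and the index is the
  Spearman correlation of window midpoint with P/E. Being rank-based it is
  invariant to monotone rescaling of the scores. Note that for an
  *uninformative* model the index is a rank correlation across roughly
  1/window-width effectively independent windows, so single values scatter
  widely around zero; only its expectation is zero.
* **AUC** by the rank statistic with tied ranks averaged (equivalently the
  probability a random presence outranks a random absence; the test suite
  checks this against brute-force pair enumeration).
* **Kappa and TSS** from the 2×2 table at a probability threshold. The
  source study never states its threshold; the default is the cut
  maximizing TSS on the evaluated data, recorded in the report, which is
  common SDM practice and reproducible.

### Kriging downscaling

Coarse-cell centers are treated as point samples. An exponential
variogram `γ(h) = nugget + sill·(1 − exp(−h/range))` is fitted by weighted
least squares to 15 empirical lag bins (weights = pair counts, lags up to
half the maximum distance), and each fine-cell center is predicted by
ordinary kriging from its nearest 32 samples. With γ(0) = 0 on the system
diagonal the predictor is exact at sample locations regardless of the
fitted nugget; outputs are clipped to [0, 1] for suitability surfaces
(disablable). A constant input short-circuits to a constant output since
the empirical variogram is degenerate there.

## The dispersal automaton

State per cell: empty / occupied (with age since colonization) /
decolonized / barrier / unsuitable. One annual update (in this order):
ages increment; every colonizable cell passing the invasibility gate is
colonized with the propagule-pressure probability
`1 − ∏ᵢ (1 − D(dᵢ; λ))` over mature sources within `sdd_max`; then LDD
events fire (per-source Bernoulli, uniform direction, uniform distance in
(`ldd_min`, `ldd_max`]) and land wherever the grid, land cover and
invasibility allow. New colonists enter at age 0, so with the default
one-year maturity they disperse from the following year.

Parameter defaults follow the published broomsedge parameterization:
λ = 0.005 m⁻¹ with a 600-m SDD cap — the kernel retains exp(−3) ≈ 5% at
the cap, honouring the "99% of seeds disperse short" definition without
separate seed bookkeeping — LDD in (600 m, 10 or 30 km], one-year
maturity, ten replicates.

Open design points and the choices taken:

* **LDD frequency units.** The source literature oscillates between
  percentages (0.1%, 0.05%, 0.01%) and bare numbers ("frequency of 0.05");
  its own footnote ("0.1, 0.05, or 0.01 events out of 100") supports the
  percentage reading. `ldd_freq` is therefore a plain per-occupied-mature-
  cell annual probability (0.05% → 0.0005), the MigClim convention. No
  rescaling is ever applied silently; configs state the probability.
* **Propagule combination** uses the independent-source complement rule —
  the standard CA formulation when only the kernel is specified.
* **Invasibility** is a hard gate by default (colonizable iff suitability
  ≥ 0.5); a continuous mode multiplying colonization probability by
  suitability is available (`continuous=True`).
* **Barriers** are "weak" by default: forest cells can never be colonized
  but do not block straight-line flight over them. A "strong" mode
  (`strong_barriers=True`) blocks any source→target segment that crosses a
  barrier cell, tested by sampling the segment at quarter-cell steps.
  "Unable to disperse through" is read as non-colonizability in the
  default because seed rain over a forest edge is physically plausible for
  anemochorous seeds.
* **Decolonization** happens only when the active suitability layer
  switches at a period boundary: occupied cells falling below the gate are
  marked decolonized (and may be recolonized later). The initial, surveyed
  distribution is never decolonized at year 0 — the survey outranks the
  model where they disagree. Decolonization can be disabled, restoring a
  monotone occupied set.
* **Determinism.** Replicate r draws from a generator seeded with
  `SeedSequence((master_seed, r))`; within a step, draws are consumed in a
  fixed order (the full SDD uniform field in raster-scan order, then LDD
  Bernoulli/direction/distance per source in raster-scan order), so
  results are bit-reproducible and independent of any internal iteration
  scheme.

The SDD update is computed for all cells at once by convolving the mature
occupancy indicator with a window of `log(1 − D)` values (complementary
log-probability is additive over sources), which keeps a 200 × 200 grid
step under a millisecond; the per-cell reference implementation
(`sdd_colonization_prob`) is retained and cross-checked in the tests.

## Synthetic landscapes

The generator emulates a fragmented agricultural-forest mosaic: smooth
random fields (Gaussian-filtered white noise at the requested
autocorrelation range, rank-transformed to the target marginal) provide
covariates; land-cover classes are placed as thresholded smooth fields —
contiguous blobs, not salt-and-pepper, because barrier geometry is
direction-dependent — each class claiming its requested cell fraction in a
fixed order, so realized fractions match requests to cell rounding.
Ground-truth suitability is the inverse logit of a stated linear
combination of the covariates. Default class fractions (forest 0.46,
built-up 0.11, rice paddy 0.20, water 0.03) mirror the composition of the
motivating study region, with its farmland split between paddy
(unsuitable) and open dry fields. All synthetic grids live on a local
projected frame in meters since the automaton needs metric distances.

What the generator does *not* emulate: real coastline or island geometry,
anisotropic wind fields, road networks (the human-influence covariate is
just another smooth field), temporal climate trends, and observation error
in surveys. Tests passing on these worlds therefore validate the
machinery — kernel math, constraint handling, seeding, metric
computations — not the ecological fidelity of any particular forecast.

Occurrences are sampled with probability proportional to suitability and
jittered within the cell; "observed" spread is one forward simulation of
the automaton under stated true parameters, standing in for a field
survey with perfect detection.

## LDD calibration and its identifiability limit

Calibration runs the automaton under six labelled parameter sets
(frequencies 0.001 / 0.0005 / 0.0001 crossed with ranges 10 / 30 km),
scores each replicate's final occupancy against the observed map with the
plain pixel Jaccard index (an optional buffered mode dilates the observed
layer by one cell first; the "modified" index of the source study is
undefined there, so plain Jaccard is the default and the choice is
surfaced in the output), and ranks sets by mean Jaccard. One-way ANOVA
with Tukey's HSD and a compact-letter display (letters = maximal cliques
of the not-significantly-different graph, ordered by group mean) groups
the sets.

A validation experiment (`spreadca.experiments.ldd_recovery_experiment`)
asks whether this procedure recovers known parameters: on independent
synthetic worlds, observed spread is generated under F0.05_30km and the
six sets are ranked against it. The design maximizes identifiability —
open, percolating worlds 40 km across (larger than the longest jump, so
ranges differ in shape rather than being censored), a clustered
multi-population initial distribution giving a distance gradient, and a
synthetic survey taken mid-invasion (first year observed spread covers
45% of suitable habitat), the stage at which candidate footprints differ
most. The experiment nevertheless finds, and reports, a low recovery
rate: ranking by single-survey mean Jaccard is biased toward *extreme*
parameter sets. The mechanism is simple. When simulated long-distance
foci are spatially unstructured relative to the observation, the expected
Jaccard of maps with fill fractions a (simulated) and b (observed)
behaves like `ab/(a+b−ab)`, which is monotone in a — the middle set is
never the maximizer. When the landscape channels spread strongly enough
that footprints are nested, a set that overshoots the observed fill
scores about `b/a`, while the matched set scores the run-to-run footprint
reproducibility ρ of the stochastic process; at the event rates implied
by per-cell jump probabilities of 10⁻⁴–10⁻³, ρ stays below `b/a` for the
adjacent stronger set. Identifying a middle LDD parameter set from one
survey map therefore needs information beyond a final-map similarity
ranking — e.g., dated invasion fronts, multiple survey years, or a
likelihood over jump counts. This limitation is a property of the
published calibration procedure at desk scale, not of its implementation
here; the experiment, tests and reproduction script report the measured
rate rather than assuming recovery.

## Problem sizes

The shipped experiments use grids of 40×40 to 200×200 cells (200-m
resolution), 10 replicates per parameter set, 20 recovery worlds, 20 000
Monte-Carlo replicates for the one-step oracle, and 60-year horizons —
sizes chosen so the full suite and the reproduction script each complete
in a few minutes on a single CPU while keeping every statistical check at
a meaningful scale.
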