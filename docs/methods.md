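# Methods

## Scope and model

`lisakit` performs cross-sectional spatial cluster analysis applied
longitudinally: each time point of an areal dataset is analyzed
independently with local indicators of spatial association (LISA), and the
per-time categorical labels are then compared across methods and across
time. There is no spatiotemporal model — temporal structure enters only
through the evaluation layer, which is deliberate: the per-time analyses
stay interpretable as standard LISA maps, and the longitudinal summaries
quantify their stability.

### Normalization

Each time slice is z-normalized against that slice's own mean and **sample**
standard deviation (divisor n−1). The divisor choice makes the Moran sum
`Σ_i z_i lag_i/(n−1)` coincide exactly with the classic
`(n/S0)·ΣΣ W_ij z_i z_j / Σz²` form (S0 = n for row-normalized weights) and
yields clean closed forms: the 2×2 rook checkerboard gives I = −1,
I_i = −1/4, C = 1.5, C_i = 3. Per-slice normalization (rather than pooling
the whole series) keeps each map a self-contained cross-sectional analysis;
pooled normalization is available via `RunConfig(normalization="pooled")`
for users who want values comparable across years.

All statistics consume z only, so they are invariant to affine transforms
of the raw values — which is also why the synthetic fixtures express effect
sizes in multiples of the noise sd.

### Weights

Binary contiguity (queen by default; rook available), built from shapely
boundary intersections: rook requires a shared boundary segment of positive
length, queen any non-empty boundary intersection. Defining queen
geometrically (rather than by shared vertices) guarantees queen ⊇ rook even
for T-junction geometries; on clean lattices the two definitions agree.
Weights are row-normalized (each non-empty row sums to 1, tolerance 1e-12).
Gi* uses the self-included row-normalized matrix; every other statistic the
self-excluded one. Islands — areas with no neighbors — keep empty rows,
are reported in a warning, and receive no local statistic: their results
carry an explicit *undefined* marker (NaN at the array level), never a
silent zero.

When a time point has missing (e.g. suppressed) values, the affected areas
are excluded from that time point only; the weight matrix is re-subset on
the original binary structure and re-row-normalized over the remaining
areas. No imputation is performed.

### Statistics

Local Moran's I, Local Geary's C, Getis-Ord Gi and Gi*, plus the three
global companions (Moran's I, Geary's C, General G). The Gi/Gi* forms are
the Ord–Getis z-statistics; for Gi the leave-one-out sd S(i) uses the
population divisor over the n−1 non-focal values, a convention that is
immaterial here because inference is purely permutation-based. One caveat
worth knowing: General G is evaluated on z-scores, whose cross-product
denominator `(Σz)² − Σz²` is negative, so the raw G value's sign is not
interpretable on its own — its label ("high-clustering"/"low-clustering")
follows the tail of the permutation distribution, like everything else.

### Permutation inference

Global statistics: total randomization (the z vector is shuffled across
locations M times). Local statistics: conditional randomization — the focal
value stays fixed and the remaining n−1 values are drawn without
replacement onto the neighbor slots. M defaults to 999, giving p*
granularity of 0.001 against the default alpha of 0.05.

The pseudo p-value is tail-wise one-sided with min-tail selection and no
doubling: `p* = (min(R_up, R_down)+1)/(M+1)`. Because the observed
statistic's rank among the M+1 exchangeable values is uniform under the
null, this rule flags ≈ 2·alpha of null locations (each tail is tested at
alpha). Users wanting a strict family rate of alpha should halve alpha.
Statistics are additionally standardized against the permuted set (sample
sd; undefined when the permuted set is degenerate, in which case the
location is never significant), and nearest-rank empirical bounds at alpha
per tail are reported for display. A Gaussian KDE (Silverman bandwidth)
of the permuted set is available for density displays.

Reproducibility: every permutation stream is seeded by SeedSequence entropy
`(master seed, CRC32(time label), stream tag, location index)`. Streams are
therefore independent of iteration order, of the enabled-method set (all
methods at one location share the same draws — valid because row-normalized
binary weights are exchangeable within a row), and of the order of time
points in the input file. Two runs with the same seed are byte-identical.

### Labels

Local Moran: significant results split by the signs of (z_i, lag_i) into
high-high / low-low (clusters, z·lag > 0) and high-low / low-high
(outliers, z·lag < 0). An exactly-zero product (measure-zero on continuous
data) is treated as a cluster, with z = 0 counting as positive — fixed
tie-breaks, documented for reproducibility. Local Geary: significant lower
tail is positive spatial autocorrelation (high-high / low-low by quadrant,
otherwise *other-positive*); significant upper tail is *negative*, which
cannot be localized further. Gi/Gi*: significant upper tail = hot-spot,
lower = cold-spot.

Aggregation canonicalizes hot-spot ≡ high-high and cold-spot ≡ low-low,
then: high and low evidence together → *contradiction*; exactly one of
{high, low, outlier} → that category, with agreement = supporting methods /
methods with a defined label (*other-positive* and *negative* neither
support nor block, since they do not commit to a direction); several
primary classes, or only non-directional significant labels → *mixed*;
nothing significant → *none* (agreement 0). *negative* deliberately does
not contradict a high/low cluster claim: Gi* detects hot/cold spots rather
than autocorrelation, and a low-valued location inside a high neighborhood
can legitimately be a Gi* hot-spot and a Geary *negative* at once.

### Longitudinal evaluation

Three summaries over the (area, time, method) label tensor, all using
canonical label equality and dropping undefined/missing cells from
denominators:

- **Between-method comparisons** (pooled over time points): each unordered
  method pair at each cell is classified as *both-same*, *similar*
  (significant, non-identical, non-contradictory — e.g. high-high vs
  other-positive, or negative vs low-high), *other-not-significant*
  (exactly one side not significant), or *contrasting* (high vs low
  cluster, or cluster-type vs outlier-type). Fractions are broken down per
  involved label, alongside the full pairwise matrix P(L, L′).
- **Final-time agreement**: per location, whether the label k steps before
  the final time equals the final label; the lag-0 anchor is identically 1.
- **Temporal co-occurrence** per method: Q(L, L′) = fraction of locations
  ever labeled L that carry L′ at some *other* time; Q(L, L) requires L at
  two or more distinct times (the "other time point" is read literally).

## Synthetic fixtures

Regular lattices of unit squares with iid Gaussian noise and additive
planted effects: a static block (persistent hot region), a linear trend
block (gradually emerging cluster), and a single-cell single-time spike
(transient anomaly). The stock fixture is a 12×12 grid, 10 time points,
unit noise, seed 42, with block effects of ±3 noise-sd and a spike of
+6 noise-sd — magnitudes chosen to mirror, respectively, a clearly elevated
mortality region and a sudden small-population rate spike.

What the fixtures do not emulate: irregular polygon topologies, spatially
correlated noise, value distributions with heavy tails, or systematic
suppression patterns. Passing the planted-pattern tests therefore shows the
machinery recovers known structure under clean conditions, not that any
particular real dataset's labels are correct.

A noteworthy property verified by the spike experiment: under conditional
randomization a single-cell spike cannot make the spiked cell itself
significant (its value is fixed in every permutation), and it makes each
neighbor only marginally significant, because the spike value sits in the
neighbor's permutation pool and is drawn into a k-neighbor set with
probability k/(n−1) regardless of the spike's magnitude. Detection of such
transients is therefore structurally capped — an argument for longitudinal
inspection over single-map inference.

## Numerical choices and problem sizes

- Row-sum tolerance 1e-12; statistic-vs-brute-force oracle agreement
  asserted at 1e-10 on random 8×8 lattices.
- Degenerate denominators (uniform Gi* weights, constant non-focal values,
  vanishing General G denominator) return undefined markers.
- Permutation draws use `argpartition` on random keys — a uniform random
  k-subset; arrangement within the subset is irrelevant under equal
  within-row weights.
- Test and acceptance problem sizes (8×8 to 12×12 lattices, 100–200
  replicate lattices, M = 999) were chosen so the whole suite completes in
  a few minutes on one CPU while keeping Monte-Carlo error well below the
  asserted margins.

## Known limitations

- No multiple-testing correction across locations, methods, or time points;
  labels at alpha = 0.05 are exploratory.
- No distance-band or k-nearest-neighbor weights; contiguity only.
- Geometries are used as given (GeoJSON lon/lat); no reprojection or repair.
- The evaluation layer treats time labels as ordinal; no calendar
  arithmetic or unequal-spacing adjustment.
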