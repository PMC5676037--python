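# Methods

This note documents the models, estimators and design choices behind each
stage of the pipeline, what the synthetic generators emulate, and the known
limitations of both.

## Coordinate conventions

All genomic coordinates are 0-based half-open internally.  BED input is
consumed as-is; feature tables may be declared 1-based in the config and
are shifted on read.  The chromosome is circular with length `L`; *oriC*
defaults to position 0 and *ter* to `L/2`, so the linear map's two edges
meet at the origin.  Distances are shortest-arc:
`d(a, b) = min(|a − b|, L − |a − b|) ≤ L/2`.  Intervals running past `L`
are split into two sub-intervals sharing a name, which keeps all downstream
interval logic linear.

## Replicate confirmation and enrichment filtering

A consensus peak requires ≥ 1 bp overlap with at least one interval from
each IP replicate and no overlap with any control-strain peak.  The default
consensus interval is the *intersection* of the overlapping replicate
intervals (the minimal region both replicates support); a `union` policy is
available.  Candidates from different replicate pairs that overlap each
other are merged, and provenance (the contributing replicate intervals with
their fold enrichments) is retained.  Enrichment filtering keeps a
consensus peak when all contributing intervals reach the fold threshold
(`require_both`, the default) or when any does.

Touching-but-not-overlapping candidate intervals are kept separate
(strictly `start < end` overlap); the test-suite oracle uses the same
convention via an order-independent fixed-point merge.

## Spacing, density and the ori→ter bias test

On a circle the `n` midpoint-to-midpoint gaps sum to `L`, so mean spacing
is exactly `L/n`; the full gap list is also returned for dispersion
analysis.  The density profile reports per-bin peak counts (default bin
100 kb, ~70 bins on a 7 Mb genome — enough resolution without empty-bin
noise) and, per peak, its length and the inverse gap to its successor,
using midpoints because they are robust to the heavy-tailed width
distribution.

The bias statistic is the Spearman rank correlation between per-bin counts
and the bin midpoint's circular distance from *oriC*.  The null hypothesis
(no positional preference) is simulated by re-placing the `n` midpoints
uniformly on the circle; the p-value is two-sided,
`p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (1 + n_perm)`, with `n_perm ≥ 100`
enforced and 1,000 the default.  A negative statistic with small p means
density decays from origin to terminus.  Rank correlation was chosen over
a parametric slope because bin counts are overdispersed, and the
permutation null makes no distributional assumption.

## Peak annotation

The promoter window of a feature is the 150 bp immediately upstream of its
strand-aware start (upstream of the `end` coordinate on the − strand),
i.e. positions −150…−1 relative to the start, wrapped circularly at the
map edges.  Categories are assigned by two literal predicates with no
precedence: *promoter* = the peak intersects any promoter window;
*gene_body* = the peak begins **and** ends within one feature body;
*mixed* = both hold; *intergenic* = neither.  The containment requirement
means a peak straddling a gene boundary and its promoter window is
*promoter*, not *mixed* — the predicates are applied exactly as defined.

## Single-particle tracking

Linking is greedy nearest-neighbour between consecutive frames: globally
closest pairs within `r_max` link first; ties break on the canonical
(frame, x, y) ordering of localizations, so results are deterministic.
There is no gap closing — a blinking molecule yields two tracks — and
tracks shorter than `min_steps` (+1 localizations) are discarded.  The
default `r_max = 3·√(4·D·Δt)` makes a missed link a >3σ event for the
fastest expected population.

The per-track MSD is the mean of the first four single-frame squared
displacements (`n_steps = 4`), and `D* = MSD / (4 Δt)`.  A lag-averaged
variant (mean over lags 1–4 of `MSD(τ)/τ`) is available by config; it has
lower variance and the same expectation for free diffusion.  D* is
*apparent*: confinement inside a 0.7 µm-wide cell caps the transverse MSD
and biases D* downward for fast particles, while localization error `σ`
adds a noise floor `σ²/Δt` (for independent per-frame errors the expected
squared step is `4DΔt + 4σ²`).

Classification is a fixed threshold: immobile iff `D* < d_threshold`,
default 0.1 µm²/s, chosen midway (in log scale) between the default
generator's noise floor (0.02 µm²/s) and its mobile population
(~0.5 µm²/s).  An antimode-based data-driven threshold estimator is
provided, but the fixed config value is the reproducible default and is
recorded in the run manifest.  Fractions and the diffusing:immobile ratio
are counted per track, not per localization.

Normalized cell coordinates: `ℓ ∈ [0,1]` is the projection onto the
pole-to-pole axis over cell length, measured from the designated
(old/distant) pole; `w ∈ [−1,1]` is the signed perpendicular offset over
the half-width.  The folded coordinate `|ℓ − 0.5|` supports pooling cells
with arbitrary pole orientation.  Points beyond a configurable tolerance
(default 0.05 normalized units) outside the footprint are excluded and
counted.

## Nucleoid profiles and condensation

Profiles are 1D intensity samples at fractional long-axis positions; the
image-based extractor averages pixels in stripes perpendicular to the
pole-to-pole axis.  Cohort averaging resamples every profile onto a fixed
100-point fractional grid (cells differ in length; fractional coordinates
make cohorts comparable) and reports the pointwise mean with a
t-distribution 95% CI.

Condensation extent: background is the median intensity over the 5% of
positions nearest each pole; the threshold is 20% of the
background-subtracted maximum; the extent is the distance between the
outermost threshold crossings, linearly interpolated between grid samples
for sub-grid precision.  Outermost crossings (rather than the largest
contiguous run) deliberately span two-lobe nucleoids around chromosome
segregation.  The statistic is invariant to positive scaling of the
profile.  Two degenerate cases: a profile with no positive signal has
extent 0 (flagged); a profile with positive signal but no contrast above
the pole background is taken to fill the whole cell (extent 1), since
"background equals signal" there means the stain reaches the poles.

Colocalization is the Pearson correlation of two background-subtracted
channel profiles on the common grid.  Time-lapse series are split at each
division (sister-chromosome separation) frame; empty segments are skipped
with a warning, and each remaining segment gets a mean extent with a 95%
t-CI.

## Abundance arithmetic

The standard curve is an ordinary least-squares line
`intensity = slope·ng + intercept` (≥ 3 points; a non-positive slope is
warned about, not fatal).  Sample mass is the inverted line; molecules =
`ng·10⁻⁹ / m · N_A` with monomer mass `m` defaulting to 48 kDa (an
EGFP-tagged small DNA-binding protein; 47 kDa for the mCherry fusion);
per-cell counts divide by lane CFU.  The expected binding interval is
`L / (copies / monomers_per_binding_unit)`; the default unit factor of 1
means the input is already in binding units (e.g. dimers) — no
stoichiometry conversion is ever applied implicitly.

## Synthetic data: what it emulates, and what it does not

**Peaks.**  True binding-site midpoints follow an inhomogeneous point
process on the circle, default linear intensity
`λ(d) ∝ 1 − β·d/(L/2)` with `β = 0.6` (about 65% of sites in the
ori-proximal half), sampled by rejection.  Widths are log-normal (median
400 bp, σ = 0.8) floored at 150 bp — the sonication-fragment scale below
which called peaks do not occur — which leaves ~13% of peaks ≥ 1 kb.
Replicates observe each site with 50 bp Gaussian midpoint jitter and 2%
independent dropout; fold enrichments share a per-site log-normal true
value (median 5.5, σ = 0.6, so roughly half the confirmed set clears a
5-fold cut in both replicates) with 10% replicate noise.  Control peaks
are uniform and by default constructed disjoint from the truth.  Because
replicate confirmation cannot recover a site absent from a replicate, the
recovery guarantee (≥ 95%) is stated against sites present in both
replicates; overall recovery is bounded near 96% by the dropout rate.

**Tracks.**  The immobile fraction is an exact composition
(`round(n·fraction)` tracks), so recovery tests measure classification
error rather than binomial label noise.  Immobile emitters are a fixed
uniform point blurred per frame by `σ = 20 nm`; mobile particles take
Brownian steps (`D = 0.5 µm²/s`, `Δt = 20 ms`) mirror-reflected at a 2D
spherocylinder footprint (flat sides folded, cap overshoots reflected
radially).  Track lengths are 5 + geometric (mean 4 extra frames,
emulating bleaching).  Photoactivation is sparse: tracks within a cell
occupy disjoint frame windows separated by ≥ 3 dark frames, so linking is
unambiguous — real PALM data has occasional simultaneous activations the
generator does not produce.  Defaults give 384 tracks, matching the scale
of a single-condition experiment.  Classification at these defaults shows
a small (+1–2 point) upward bias in the recovered immobile fraction from
confinement-slowed mobile tracks; this is a property of the apparent-D*
method itself, not of the generator.

**Profiles.**  Each cell is a plateau with logistic edges (softness 0.01
cell lengths) plus Gaussian noise (σ = 0.05 of plateau height), centred
near midcell with jitter.  The occupancy parameter is defined as the
plateau width *at 20% of plateau height* — the same level the extent
estimator thresholds at — so "occupancy 0.75" is recovered without bias by
construction and noise-free recovery is exact.  Channel 2 is the clean
channel-1 structure scaled by a coupling factor plus independent noise.
The generator does not model diffraction blur, photobleaching gradients,
or cell-to-cell intensity variation, so passing tests demonstrate
estimator correctness on the stated model, not robustness to real optics.

Every generator draws from a single `numpy` Generator seeded from the
config; identical configurations give bit-identical outputs.

## Problem sizes and determinism

The test suite and the acceptance script run the generators at their
default study-scale sizes: 600 peak sites, 384 tracks, 100 profile cells,
10,000 free tracks for estimator calibration, 1,000 permutations per bias
test, and 20–50 seeded replicates for power/size estimates.  The CLI
writes a `manifest.json` containing the config hash, seed, input digests
and output digests with relative paths only, so two runs with the same
seed and config are byte-identical.

## Known limitations

* The replicate-confirmation overlap rule (≥ 1 bp, intersection) is a
  minimal formalization; published peak sets may have used different merge
  conventions, so absolute confirmed counts are convention-dependent.
* The bias test conditions on the observed number of peaks and treats
  peaks as points (midpoints); very long peaks spanning bin boundaries are
  assigned to one bin.
* D* from four steps is a high-variance estimator (χ²₈-scaled); per-track
  classification near the threshold is noisy even when population
  fractions are recovered accurately.
* Condensation extent depends on the relative threshold; the default 0.2
  is explicit in results and the manifest, and cohort comparisons should
  hold it fixed.
* The image-based profile extractor assumes a straight cell axis; bent
  cells need upstream segmentation, which is out of scope.
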