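# Methods

This note documents the models implemented in phylogeokit, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
tests do and do not establish.

## Genetic distances and dating

Pairwise distances use the Kimura two-parameter model with pairwise
deletion: any site where either sequence carries a gap, N, or IUPAC
ambiguity is excluded from that pair's comparison (the convention of the
standard AMOVA software this pipeline interoperates with).  Among-site rate
heterogeneity is handled by the Jin & Nei (1990) gamma form; the shape
default α = 0.68 is a typical maximum-likelihood estimate for a concatenated
mitochondrial protein-coding alignment and is exposed as a parameter.  When
1 − 2P − Q or 1 − 2Q is non-positive the pair is reported as saturated, with
the offending pair named — distances are never silently truncated.

Between-group divergence is corrected for shared ancestral polymorphism
with Nei's net divergence d_A = d_xy − (d_x + d_y)/2, where d_x and d_y are
within-group means over unordered pairs (a single-member group contributes
0 by convention).  d_A can be negative when within-group diversity exceeds
the between-group mean; it is reported as-is, and the dating layer flags it
as "0 or unresolved" rather than clamping.

Dating assumes a strict clock on between-lineage divergence: T = d_A/rate
with rate 0.021/Myr and an interval from rate ± sd (default sd 0.001).
Dividing by the pairwise rate (not the per-lineage rate) is the convention
that makes a corrected divergence of 0.10 correspond to 4.8 Myr.  Reports
round to one decimal; stored values never round.

## AMOVA and neutrality statistics

The three-level AMOVA follows Excoffier, Smouse & Quattro (1992): sums of
squared deviations computed directly from the distance matrix, variance
components from expected mean squares with unequal sample sizes, and
Φ_CT = σ²_a/σ²_T, Φ_SC = σ²_b/(σ²_b+σ²_c), Φ_ST = (σ²_a+σ²_b)/σ²_T.
Distance entries are used directly as squared deviations (the convention
for user-supplied molecular distances; `square_entries=True` squares raw
distances instead).  Negative components and negative Φ are reported
unmodified.  Permutation schemes: whole sites among basins (Φ_CT), samples
among sites within basins (Φ_SC), samples among sites across the design
(Φ_ST); p-values include the observed arrangement in numerator and
denominator, with 10,000 permutations and an explicit seed by default.
Note that a design with one site per basin leaves the Φ_CT site-permutation
test without power (every permutation reproduces the same grouping): its
p-value is then 1 by construction, and inference should rest on Φ_ST.
Statistics that cannot be computed (a basin with fewer than two samples, a
zero-variance matrix) are returned as an explicit `Undefined` value carrying
the reason, never as a silent 0.

π is the mean raw pairwise difference count, with Tajima's (1983) sampling
variance for its SD.  Per segregating site the minimum substitution count
is (number of observed unambiguous states − 1); a transition is counted for
each purine pair and each pyrimidine pair fully present, the remainder
being transversions.  Tajima's D uses the standard 1989 constants and is
undefined for n < 4 or S = 0.  Fu's F_s computes
S′ = Pr(K ≥ k_obs | θ = π) under the Ewens distribution with unsigned
Stirling numbers of the first kind held as exact integers and combined in
log space (stable to n in the hundreds); F_s = ln(S′/(1−S′)), with exact 0/1
cases mapped to signed infinities and flagged.

## Median-joining networks

The network construction follows Bandelt, Forster & Röhl (1999): the
ε-relaxed minimum spanning network (an edge survives when its weight is
within ε of the minimax-path weight between its endpoints), followed by
iterative addition of quasi-medians for feasible triplets — two neighbours
of a common node — keeping, per round, the candidates within ε of the
cheapest connection cost; finally, median vectors of degree ≤ 2 are pruned
to stability.  Quasi-medians take the per-column majority state; columns
with three distinct states fall back to the state of the first node in
label order, so only majority columns can move a median off its parents.
ε defaults to 0 (the usual software default).  Every tie-break is
lexicographic in node label, making output deterministic and invariant to
input order.  Distances count only unambiguous positions; how ambiguous
bases and indels should weight network edges is genuinely underdetermined,
and excluding them is the conservative choice.

## Landscape resistance and isolation by distance

The friction model prices movement through a cell as
y = 1.4142·e^(0.0035·x) of elevation x in metres, floored at 1 (sea level
and below) and impassable above 2300 m — the focal species' elevational
ceiling.  Note the printed cost-range endpoint sometimes quoted with this
model (5096 at 2300 m) is inconsistent with the formula itself (≈ 4432);
the formula is taken as authoritative, and `FrictionModel.calibrated()`
provides the variant that anchors the cap cost at 5096 exactly.  A linear
ramp with the same ceiling is available (`mode="linear"`), since the choice
of ramp rarely changes Mantel significance.

Least-cost distances run Dijkstra over the 8-connected lattice with edge
weight = mean(cost of the two cells) × cellsize × (√2 for diagonals), and
diagonal steps may not cut a corner between two impassable cells.
Unreachable pairs are ±inf flags, never an arbitrary large number.  Sites
are mapped through an equirectangular projection (x = 111.32·cos(ref_lat)·lon
km, y = 110.57·lat km) and snapped to the nearest passable cell within 5
cells (configurable); an unmappable site is an error naming the site.

The Mantel statistic is the Pearson correlation over off-diagonal unordered
pairs, with one-tailed significance from joint row/column permutations
(observed included).  The IBD diagnostic fits ordinary least-squares slopes
of genetic on geographic distance separately over within-basin site pairs
(per basin with ≥ 3 sites) and over all between-basin pairs: vicariance
predicts positive within-basin slopes with a flat-to-negative between-basin
pattern, because between-basin divergence reflects barrier age rather than
distance.

## Chronograms and dispersal classes

Nonparametric rate smoothing (Sanderson 1997) converts a substitution tree
to a chronogram: node ages minimize the summed squared differences between
each branch's rate and its descendant branches' rates; at the root, where
no ancestral branch exists, the term is the squared deviation of the child
rates from their mean.  The root age is fixed (default 5 Myr) and tips sit
at 0.  Ages are parameterized as logit-transformed fractions of the parent
age — the parent > child constraint holds by construction — and optimized
with L-BFGS from a clock-proportional start plus 4 random restarts,
tolerance 1e-9.  Zero-length branches are floored at 1e-8 substitutions to
keep local rates identifiable (warned in the contract, not silently).

Tip locations are modelled as independent 2-D Brownian motion along the
chronogram with branch variance σ²_class × duration.  The likelihood is
computed by Felsenstein's pruning algorithm on phylogenetic contrasts —
REML, with the root location profiled out — which matches the dense
tree-covariance multivariate-normal REML likelihood to numerical precision
and avoids the downward bias of jointly maximizing over an unknown root.
Per-class rates are optimized on the log scale (L-BFGS-B, bounds e^±46)
from a closed-form single-rate moment start with optional random restarts;
a rate collapsing to the lower bound (all tips coincident) is flagged as a
boundary fit.  Nested class models are compared by 2ΔlnL against χ² with
df = difference in class counts.  The per-generation dispersal distance is
defined as ψ_c = √(σ²_c·g), the per-axis SD of one generation's
displacement, with generation time g defaulting to 1 year (1e-6 Myr) —
"mean per-generation dispersal distance" has no standard closed definition,
so the definition used is stated here and exposed as a parameter.  The
dispersal–range-size test is the Pearson correlation of ψ_c with √(basin
area), two-sided p from the t-transform with n − 2 df.

## The synthetic-data generator

`synthgen` produces datasets with exactly the structure the analyses
assume, so recovery tests have known truth:

- **Genealogy**: a censored Kingman coalescent inside a dated basin tree.
  Within each population, pairs coalesce with expected pairwise waiting
  time `within_basin_Ne_scaled` (Myr); lineages surviving to a split age
  are handed to the merged population, so split ages are never violated.
  The scale-0 limit collapses within-population coalescence instantly.
- **Sequences**: K2P simulation with transition/transversion ratio κ
  (default 8, a realistic mitochondrial value) and continuous
  Gamma(α, 1/α) site-rate multipliers (α default 0.68, matching the
  distance model), rate 1.05%/site/Myr per lineage — half the 2.1%/Myr
  between-lineage clock, so simulated data match the dating convention.
  Default loci of 135 + 242 + 195 bp concatenate to 572 bp.
- **Geography/DEM**: the default scenario places seven basins on a
  synthetic island (three sites each, 8 samples per site, 168 total) with
  splits from 0.5 to 5 Myr and a root capped at 6 Myr; ridge polylines
  rasterize at 3500 m with a half-width of one cell, so barriers are ≥ 2
  cells thick and block 8-connected passage.  Grids are plain lowland
  (100 m) elsewhere: the generator emulates barrier topology, not terrain
  texture.

Everything is deterministic given the seed.  What the generator does *not*
emulate: post-split migration, recombination, selection, sequencing error,
uneven sampling, or realistic elevation fields — so passing recovery tests
demonstrates correctness of the estimators under their own assumptions, not
robustness to violations of them.

## Verification strategy and problem sizes

Every nontrivial computation is checked against an independent oracle:
AMOVA components against longhand SSD arithmetic (≤ 15 samples), Dijkstra
against exhaustive branch-and-bound path enumeration (≤ 6×6 grids), the
pruning likelihood against dense-covariance REML (≤ 10 tips, and 50 tips in
fits), Fu's F_s against exact-rational enumeration of integer partitions
(n ≤ 8), NPRS against a dense grid search (4 tips), median vectors against
brute-force Steiner enumeration (3 sites).  Calibration studies use 500
null replicates (Mantel at n = 20 with 199 permutations; the 1-vs-5-class
LRT on a 50-tip chronogram) and require the empirical type-I rate at
α = 0.05 to lie in [0.03, 0.07]; recovery studies use 20 replicates (clock
date at 1000 bp within 15% on the mean; σ² at 50 tips within 30% on the
median) and 1000 neutral coalescent replicates for Tajima's D (n = 20,
θ = 5, mean required in (−0.3, 0.1)).  These problem sizes keep the full
suite fast while leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

- Pairwise deletion can make the distance matrix non-Euclidean; AMOVA uses
  it regardless, as the field's standard tools do.
- The Φ_SC/Φ_ST labelling follows the conventional strata definitions;
  published tables sometimes swap these labels, so compare definitions, not
  symbols.
- Median-joining with ε > 0 can grow dense networks on large haplotype
  sets; the implementation recomputes the ε-network per round and is meant
  for the tens-of-haplotypes scale typical of single-species surveys.
- The diffusion model ignores coastline and barrier constraints on
  dispersal paths (Brownian motion is unbounded), and the equirectangular
  projection is only appropriate at sub-continental extents.
- NPRS is a penalty method, not a probabilistic clock model; fixed root age
  propagates no uncertainty into downstream dispersal estimates.
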