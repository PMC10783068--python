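# Methods

This note documents the models implemented in `hadal`, the defaults
they ship with, what the synthetic-community generator does and does
not emulate, and the numerical choices that were genuinely open.

## Data model

The pipeline operates on three objects: an `AbundanceTable` (taxon ×
sample integer counts, optionally carrying a domain/lineage taxonomy),
a `SampleMetadata` table (depth in m, temperature in °C, salinity, DO,
pH, nutrient concentrations, pore-size fraction in µm), and a rooted
phylogeny with branch lengths whose tips are the taxon ids.  All
identifiers are opaque case-sensitive strings; table orientation is
never guessed (square tables are ambiguous), and missing Newick branch
lengths are set to 0 with a warning rather than silently treated as
unit lengths, which would distort every phylogenetic distance.  A stem
edge above the root is dropped on read: it cannot lie on any
tip-to-tip path and would otherwise inflate the UniFrac denominator.

## Preprocessing

ASVs seen in fewer than 2 samples or with fewer than 5 reads in total
are removed (both knobs configurable); the filter is idempotent.
Rarefaction subsamples each sample without replacement to a common
depth (default 16,000 reads) via multivariate hypergeometric draws, so
rarefied counts never exceed the originals and zeros stay zero.
Abundant/rare classes use the common literature convention — mean
relative abundance ≥ 1 % abundant, < 0.01 % rare — as defaults, since
no single standard exists; both cutoffs are parameters.  The hadal/
upper-water boundary defaults to 6,000 m, the standard definition of
the hadal zone, with depths exactly at the cutoff classed hadal.  The
network transform is ln(relative abundance + ε) with ε equal to half
the smallest nonzero relative abundance in the table: scale-aware,
defined at zero, and invariant to per-sample count scaling.

## Alpha diversity, niche breadth, factorial tests

Shannon entropy is in nats so that Pielou evenness is exactly
H/ln S (the log base is a parameter); Pielou is undefined (NaN) for
single-taxon samples.  Chao1 is bias-corrected,
S + F₁(F₁−1)/(2(F₂+1)), which stays finite when no doubletons occur;
the classic form is available by flag.  Levins breadth for taxon *i*
uses its across-sample proportions P<sub>ij</sub>:
B<sub>i</sub> = 1/ΣP²<sub>ij</sub> ∈ [1, n_samples].  The community
aggregate B<sub>com</sub> is the unweighted mean over taxa by default;
an abundance-weighted mean is offered because the aggregation level is
a genuine free choice.  The two-way ANOVA uses Type-I sums of squares
(exact decomposition on balanced designs, verified against a
cell-means oracle), hard-errors on empty crossed cells, reports F = ∞
with a flag when the residual mean square vanishes, and attaches Tukey
HSD comparisons.  Spearman correlations use midranks; for n < 20 the
p-value is a two-sided label-permutation test (default 9,999 draws)
rather than the t approximation.

## Beta diversity

Jaccard works on presence/absence, Bray-Curtis on relative abundances,
and the two UniFrac variants on branch lengths of the shared tree; the
weighted variant is normalized so all four metrics live on [0, 1].
All four are tested to 1e-10 against brute-force per-branch/per-pair
oracles.  NMDS is nonmetric MDS with isotonic regression reporting
Kruskal stress-1, best of 50 random starts by default (1-D embeddings
in particular need many starts to escape local minima), 300 iterations,
1e-7 tolerance.  ANOSIM ranks the full distance matrix,
R = (r̄_between − r̄_within)/(M/2) with M = n(n−1)/2, and permutes group
labels with a seeded generator; the p-value carries the +1 correction
and never returns 0.

## Phylogenetic null models

MNTD is the mean distance from each taxon present to its nearest
present neighbour (abundance-weighted by flag); MPD the mean over all
present pairs.  The null model is whole-tree tip-label shuffling —
equivalently a joint permutation of the patristic matrix — which is
the standard choice when nothing restricts the species pool; pool
restrictions are left to the caller by subsetting the tree.  999
randomizations by default with a floor of 99; an explicit permutation
array can be supplied, which the tests use to compare against
exhaustive enumeration of all 120 permutations of a 5-tip tree.
βMNTD between samples A and B averages, in both directions, the
abundance-weighted distance of each taxon to its nearest taxon in the
other sample; weights are within-sample relative abundances.  Pairs
sharing no taxa remain defined through the tree.  βNTI standardizes
βMNTD against the same null.  Degenerate nulls (spread at float-noise
level — e.g. a sample containing every tip, or two identical samples,
both of which are shuffle-invariant) yield NaN with a warning rather
than ±∞.  Sign conventions are asserted on constructed cases:
clustering beyond the null is negative, overdispersion positive.

## Sloan neutral community model

Under zero-sum neutral dynamics with immigration rate m into a local
community of size N, the stationary relative abundance of a taxon with
metacommunity mean p is Beta(Nmp, Nm(1−p)), so its detection
probability above limit d is F(p) = 1 − I_d(Nmp, Nm(1−p)).  The fit
minimizes squared error of observed occurrence frequencies over
log₁₀ Nm ∈ [0, 7] (coarse grid scan plus bounded refinement of the
best basins — the SSE surface can plateau when occupancy saturates),
reports R² on the frequency scale, and flags fits that are degenerate
(no occupancy variance) or that end on a search bound.  The detection
limit defaults to one read at the common depth, d = 1/N.  Taxa with
p̄ < d are excluded with a logged count.  The 95 % band is a Wilson
binomial interval around the predicted frequency at the sample count.

m = Nm/N requires the local community size N.  When it is unknown —
the usual situation with real data — the common per-sample read depth
is the standard proxy, and that is the default.  On simulated data the
true N is known and should be passed (`community_size=`): the proxy
estimates Nm, not m, and conflating read depth with community size
changes m by their ratio.  The recovery suite fits simulations of
N = 10,000, m = 0.1 at 16,000 reads and recovers m within ~10 %
(median) with R² ≈ 0.94.

## Multivariate regression tree

Best-first greedy growth: each split minimizes the within-node sum of
squared Euclidean distances of community rows to node centroids over
all midpoints of every sorted predictor, with ties broken by
(predictor name, threshold) for determinism; min_leaf = 2,
max depth = 6.  The community matrix is Hellinger-transformed by
default (square root of relative abundance), the standard way to make
Euclidean partitioning appropriate for counts; `"none"` is available.
Tree size is chosen by k-fold cross-validation (default 10, capped at
n) of the relative error Σ‖y − ŷ‖²/SS_total over the nested growth
sequence, optionally with the 1-SE rule.  The greedy split is verified
against an exhaustive oracle, the root-only choice against permuted
null data (≥ 90 % of null fits prune to the root), and per-predictor
explained-variance aggregation against hand-built cases.  Note that
when predictors are deterministic functions of one another (as depth
and temperature are in the synthetic metadata), attribution among them
is arbitrary — identical partitions produce exact gain ties resolved
lexicographically — so variance shares are only meaningful across
predictors that are not collinear.

## Co-occurrence networks and stability

Edges are Pearson correlations of the log relative-abundance rows,
kept when |r| meets the cutoff; taxa below a prevalence floor (default
5 samples) are excluded before correlating, and isolated nodes are
dropped.  The RMT mode scans cutoffs 0.30–0.95 in steps of 0.01,
thresholds the correlation matrix, drops rows that become isolated,
unfolds the eigenvalue spectrum through a monotone (PCHIP) fit of its
cumulative density, and chi-square-tests the nearest-neighbour spacing
histogram (30 bins, sparse tails merged) against the Poisson form
e^(−s).  The chosen cutoff is the smallest at which the spectrum
becomes and *stays* Poisson — two consecutive passing cutoffs — since
a single marginal p > 0.05 inside the GOE regime is not a transition.
If no cutoff qualifies the builder falls back to |r| ≥ 0.8 with a loud
warning.  On iid-noise tables with 20 samples the transition coincides
with the density at which the thresholded graph fragments (≈ 1 % of
pairs, the null probability of |r| ≥ 0.56), so the selected cutoff
pins edge density at that noise floor; with more samples the floor
drops accordingly.

Topology: degree, unweighted-shortest-path betweenness (igraph's exact
C implementation, Brandes-equivalent, verified against a path
enumeration oracle; networkx fallback), local clustering, CNM greedy
modularity (deterministic), component count, average degree 2E/N, and
negative-link ratio.  Hubs are ranked by abundance, degree or
betweenness with id tie-breaks.

Robustness removes ⌊fraction·N⌋ nodes — uniformly at random over
`reps` repetitions, or targeted at module hubs, defined by
within-module degree z-score Z ≥ 2.5 with highest-degree fallback when
too few qualify — and reports the share of the *original* N that still
has at least one link.  Fragmentation is
f = 1 − Σs(s−1)/(N′(N′−1)) over component sizes among the N′ remaining
nodes, tracked while the current highest-betweenness node is removed
k = 10 times with recomputation after every removal (a fixed-ranking
variant exists).  Because f is normalized by the remaining count,
removing a node from an already-small component can lower f by
O(1/N²); on study-scale connected networks the series is monotone, and
the implementation logs a warning if a run ever decreases.

## The synthetic-community generator

The generator emulates the structure of a rarefied trench survey: 8
depths (2, 500, 1,000, 1,759, 3,699, 5,367, 7,200, 8,727 m) × 2
pore-size fractions (0.22 and 3.0 µm) = 16 samples; per-domain ASV
richness at study scale (1,219 bacteria / 638 archaea / 1,039
microeukaryotes); metacommunity abundances drawn from a Fisher
log-series (realistic rank-abundance shape for amplicon data);
phylogenies simulated as unit-rate Yule trees.  Sequencing is a final
multinomial draw (default 20,000 reads ≥ the 16,000 rarefaction
depth), so column sums are exact and a fixed seed gives bit-identical
tables.

Neutral mode runs zero-sum Moran dynamics per sample: one random death
per step, replacement from the metacommunity with probability m, else
from a random local individual; local size N_L = 10,000 (large enough
for the diffusion approximation at desk scale) for 30 generations
(30·N_L steps — at m = 0.1, ten generations would leave ~15 % of the
stationary variance unbuilt and bias Nm upward).  Niche mode evolves
taxon optima by Brownian motion on the tree, standardizes them, mixes
in iid noise according to the conservatism parameter λ ∈ [0, 1], and
sets expected abundance ∝ p·exp(−(E−o)²/2σ²) on the standardized
log-depth gradient E; σ is in gradient-SD units (σ ≈ 0.15 is a strong
filter, σ → ∞ recovers metacommunity sampling exactly).  Mixed mode
blends the two expected compositions with weight w before sequencing.
The environmental covariates are smooth, oceanographically plausible
depth profiles with a few percent of noise; they exercise the
regression-tree and ordination machinery and are not a hydrographic
reconstruction.

What passing tests on these communities do show: the estimators
recover known migration rates, the null models are calibrated (βNTI
within ±2 for ≥ 90 % of neutral pairs; SES.MNTD centred on zero under
random assembly and negative under conserved filtering), and the
stability metrics obey their structural contracts.  What they do not
show: behaviour under compositional artefacts, PCR/chimera error,
copy-number variation, read-depth heterogeneity, temporal dynamics, or
cross-domain interaction structure beyond shared environmental
response — none of which the generator simulates.

## Problem sizes

The shipped test and acceptance runs use study-scale inputs where the
statistic demands them (1,000 taxa × 30 samples × 16,000 reads for
neutral-model recovery; 200 taxa × 16 samples × 999 randomizations for
the null-model calibrations; 483/467-node graphs for the network
arithmetic) and small constructed instances everywhere an exact oracle
or closed form is being checked.

## Known limitations

* The RMT criterion is a heuristic; on very small spectra (< 30
  connected nodes) the NNSD test is skipped and the scan treats the
  matrix as already noise-free.
* The neutral fit estimates Nm; m is only as good as the community
  size supplied, and read depth is a proxy.
* βNTI classification thresholds (±2) are conventions, not derived
  quantiles.
* The cascade (abundance-weighted extinction) robustness variant is
  not implemented; robustness is isolation-based.
* Tukey "letter" displays are not generated; the pairwise Tukey table
  is returned instead.
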