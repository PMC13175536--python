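# Methods

`clonekit` implements an ecological-genetics workflow for partially clonal
plants sampled on metre-grid transects and genotyped at microsatellite
loci: identify genets and their ramets, characterize the mating portfolio
(outcrossing, selfing, vegetative spread), quantify patch differentiation,
test the ramets-per-genet distribution against neutral sampling nulls, and
compare clonal spatial patterns to permutation nulls.  A forward simulator
of partially clonal populations supplies test data with known truth.

## Genet identification

**Distances.** Genotypes are diploid allele-state vectors in repeat units.
The *stepwise* distance sums, over loci scored in both genotypes, the
minimum over the two diploid allele pairings of the absolute repeat-count
differences (an exact assignment at ploidy 2; squared steps available via
`power=2`).  It is integer-valued, satisfies the triangle inequality on
fully observed genotypes, and is the scale on which the lineage threshold
is set.  *Bruvo's* distance uses per-allele `1 − 2^(−|x−y|)`, the minimum
pairing mean per locus, and the mean over shared loci; it is bounded in
[0, 1] and is used for within-patch isolation-by-distance tests.  Loci
missing in either genotype are skipped; pairs with no shared locus are
flagged incomparable and excluded from thresholding.  Genome-addition
variants of Bruvo's distance are unnecessary here because missingness is
whole-locus at ploidy 2.

**Thresholding.**  A multilocus lineage (MLL) absorbs scoring error, null
alleles and somatic mutation among ramets of one genet.  `suggest_threshold`
smooths the pairwise-distance histogram (moving average, window 3), walks
from the clonal mode at/near zero down to the valley floor, and returns the
first empty raw bin after the clonal peak (or the valley floor when no bin
is empty).  A histogram with no second mode yields 0 — strict genotype
identity — with a warning.  The user threshold always wins when given.
`assign_mlls` takes the single-linkage closure: connected components of the
graph with an edge wherever distance ≤ threshold.  Chaining is intentional
and documented — the pairwise rule "equal or less than the threshold" has
no transitive-free reading — and is tested explicitly.  MLL ids follow
first-encountered stem order, so the partition is invariant to row order up
to relabeling.  Assignment runs on the pooled matrix so lineages spanning
patches are detected globally.

**Clone correction.**  Diversity and differentiation statistics use one
representative per MLL: the member with fewest missing loci, ties broken by
lowest sample id (deterministic).  A flag allows ramet-inclusive replicates.

## Mating portfolio

**Round-robin frequencies.**  For each locus, lineages are defined by strict
identity over all *other* loci and the locus's alleles are pooled from one
representative per lineage, breaking the circularity between frequency
estimation and clone identification.

**p_sex(F) and exclusion.**  The expected frequency of a multilocus
genotype under sexual reproduction with fixation index F multiplies
per-locus terms `p² + Fp(1−p)` (homozygote) and `2pq(1−F)` (heterozygote),
clamped at zero for F < 0.  Missing data are imputed by two independent
draws from total-population frequencies before evaluation.
`exclusion_probability(p, N)` returns both `(1−p)^N` — the probability that
no chance-identical genotype occurs among N — and its complement; the
complement is the headline figure (at p = 2×10⁻⁹ and N = 935 it is
1.87×10⁻⁶).  Computation uses `log1p`/`expm1` to stay exact at tiny p.

**G_IS.**  Per locus, observed heterozygosity H_O and Nei's unbiased gene
diversity `H_S = n/(n−1)·(1 − Σp² − H_O/(2n))`, with n the count of stems
scored at that locus.  The multilocus fixation index is the ratio of sums,
`G_IS = 1 − ΣH_O/ΣH_S` (ratio-of-sums stabilizes low-diversity loci), with
2.5%/97.5% quantiles of the delete-one-locus jackknife replicates.  At a
constant 50/50 mixed mating system the equilibrium inbreeding coefficient
is the fixed point of `F' = s(1+F)/2`, i.e. `F = s/(2−s)` (= 1/3 at
s = 0.5); the simulator-plus-G_IS pipeline recovers this within Monte-Carlo
error, which is the package's main end-to-end calibration.

## Differentiation

**G''_ST.**  Per locus, H_S is the unweighted mean within-patch gene
diversity and H_T the diversity of the unweighted mean allele frequencies;
the standardized, small-k-corrected measure is
`G''_ST = k(H_T − H_S) / ((k·H_T − H_S)(1 − H_S))`.  Multilocus values
average the per-locus H_S and H_T components before applying the formula.
Plain Nei (1973) diversities are the default because they make the
boundary cases exact — identical patch samples give exactly 0 and patches
fixed for alternative alleles exactly 1; `unbiased=True` switches to
Nei–Chesser small-sample estimators, which are preferable for very small
samples but give slightly negative values for identical finite samples.

**R_ST.**  Per locus, `R_ST = (S̄ − S_W)/S̄` with S̄ the population
(ddof = 0) variance of allele size over all pooled gene copies and S_W the
n_i/N-weighted mean within-patch variance; between = total − within holds
exactly under these conventions, so the boundary cases are again exact.
Multilocus values sum the variance components over loci.

**Resampling.**  Total-population CIs are percentile bootstraps over
patches (default 5,000 draws, seeded).  Caveat: a resample that includes
the same patch twice contributes zero differentiation for that pair, so
the patch bootstrap is biased downward — markedly for G''_ST (H_S enters
the standardization), mildly for R_ST.  The interval can therefore sit
below the point estimate; it is reported as defined because it mirrors the
stated resampling design.  Pairwise R_ST carries a delete-one-locus
jackknife spread (10 loci make literal 5,000 jackknife iterations
impossible; a bootstrap-over-loci option honours large iteration counts).

**Sexual genotype null.**  Expected distinct-genotype counts under random
mating draw N multilocus genotypes per iteration (two independent alleles
per locus from patch frequencies) and count distinct genotypes; the
one-sided p-value is `(1 + #{count ≤ observed})/(n_iter + 1)`.  The tiny
closed-form case (one locus, two equifrequent alleles, N = 2 → 1.625) is
the unit oracle.

## Isolation by distance

Within patches: Spearman Mantel test between Bruvo distances of MLL
representatives and Euclidean distances between MLL ramet centroids
(arithmetic means of grid coordinates).  All MLLs enter by default,
singletons at their own point; `multi_ramet_only=True` restricts to MLLs
with ≥ 2 ramets (both readings of the sampling rule are supported because
the source descriptions conflict).  The null permutes rows and columns of
one matrix jointly; p = `(1 + #{null ≥ observed})/(n_perm + 1)` (default
9,999 permutations).  Among patches: OLS of `D/(1−D)` on great-circle
distance (haversine, sphere radius 6,378,137 m) over unordered patch
pairs, pairs at D = 1 excluded with a warning.  The non-independence of
pairwise points is acknowledged; OLS is primary because it matches the
plain-GLM convention for this test.

## Ramets-per-genet null models

Unobservable zero counts make the zero-truncated Poisson the neutral
sampling-with-replacement model for ramets per MLL.  The by-patch model
(log link on the patch factor) separates, so each patch rate solves its
own score equation `ȳ = λ/(1 − e^{−λ})` (Brent root-find; boundary fits at
all-ones data are flagged, not raised).  Standard errors come from the
analytic observed information on the log scale.  The pooled-vs-by-patch
likelihood-ratio test uses `2Δlogλ̂` against chi-squared with df = patch
count − 1; its type-I error at the study's sample sizes is ≈ 0.05
(calibration-tested).  Pearson goodness of fit uses the observed
ramet-count categories (df = categories − 1 per patch, matching the
source's accounting); expected counts that underflow to zero are floored
at 1e−12 with a warning, which correctly drives the statistic enormous in
the presence of extreme outlying genets.  Because observed-category
statistics are heavy-tailed under the true model (stray tail values meet
tiny expectations), a flagged `bin_tail` variant provides the classical
grouped statistic whose mean/df is ≈ 1 under the truth; calibration tests
use it.  The zero-truncated negative binomial alternative is fitted in
(log mean, log size); non-convergence, extreme coefficients, boundary
size, and a likelihood no better than the Poisson limit (a flat ridge in
size — the Poisson-limit signature) are detected and reported as
structured flags, never as silent estimates.  Count data clustered at one
with isolated large values — the clonal pattern — reliably trips them.

## Spatial pattern metrics

Each patch grid is a lattice of 1 m² cells holding an MLL id, EMPTY
(sampled area without the species) or OUT (beyond the grid).  Class-level
**cohesion** over the rook-connected components of an MLL's cells is
`[1 − Σp_j / Σ(p_j√a_j)] · [1 − 1/√Z]^{-1} · 100` (p = perimeter in
cell-edge units including grid-boundary edges, a = area in cells, Z =
in-grid cells including EMPTY): 0 for singletons or fully scattered
ramets, 100 as one genet fills the grid.  **IJI** measures evenness of the
focal MLL's shared edges over the other classes (other MLLs and EMPTY;
OUT contributes no edges): `−Σ(e_k/E)ln(e_k/E) / ln(m−1) · 100`, undefined
(NaN) below three classes or with no shared edge.  Adjacency conventions
(rook components and edges; EMPTY in Z and as an edge class; boundary
edges in perimeter only) are the main dialect choices a landscape-metrics
implementation must pin down; queen components are available by flag and
treating EMPTY as background can be emulated by relabeling.  Null
distributions permute the MLL labels over occupied cells (EMPTY cells
fixed), exactly preserving ramet-count frequencies (asserted every
iteration), with 1,000 iterations per patch by default.  No single test
statistic is promoted as a headline: the report carries observed values,
null distributions and per-MLL empirical quantiles.

## The simulator

The generator is a stand-in constrained by summary statistics of the
emulated stand — no generative model is available for the real data — and
it states what it does and does not mimic:

* **Gene pools.**  Ten loci with 7–29 alleles on contiguous repeat-unit
  ranges shared across patches; per-patch allele frequencies drawn from a
  symmetric Dirichlet(1), making patches independent island-model pools
  (real patches exchange migrants; simulated differentiation is therefore
  stronger than observed in the field).
* **Mating.**  Each generation an individual is, with probability s, the
  selfed offspring of a random current member (two independent gametes
  from one parent) and otherwise the union of two gametes drawn from pool
  frequencies.  After the default 20 burn-in generations the inbreeding
  coefficient is at its mixed-mating equilibrium s/(2−s).  Stepwise
  mutation (±1 repeat, probability `mutation_rate` per transmitted copy)
  acts at every transmission.
* **Clonal spread.**  Each founder genet walks from a uniform origin on
  the 4-neighbour lattice, marking visited in-grid cells as its ramets;
  off-grid steps are discarded.  Walk lengths are Poisson(c) by default;
  the field-like preset mixes the mean with a gamma of shape
  `clonal_dispersion` (negative-binomial lengths), because a fixed-mean
  Poisson cannot produce the heavy skew of real stands (median 1 with
  occasional very large genets).  Each occupied cell is sampled once;
  co-occupied cells go to the earliest-founded genet (priority effect) —
  deterministic given the seed.  No ramet death is modelled.
* **Observation.**  Per stem and locus, each allele independently becomes
  null with `null_allele_rate` (one null → visible homozygote, two →
  missing locus), then whole locus genotypes drop out at `missing_rate`
  (default 0.0165).  Random draws are consumed regardless of the rates,
  so the sampled stem set is identical across observation settings at a
  fixed seed.
* **Preset.**  `field_like()` (10 patches, 5 transects of 10–31 m,
  s = 0.5, spread 25 with dispersion 0.09, 110 founders/patch, null rate
  0.02, one genet shared between the two first patches) was calibrated by
  Monte Carlo to land near the emulated stand: ≈ 935–1,050 stems,
  ≈ 200–230 MLLs, pooled median ramets-per-MLL of 1, maxima of tens of
  ramets.  Passing tests on these data show the estimators and nulls
  behave correctly under a realistic clonal structure; they do not show
  that any particular field estimate is correct, since the generator's
  differentiation, spatial anisotropy and disturbance history are not
  matched to any real marsh.

## Numerical and reproducibility choices

All stochastic routines take a seed or `numpy.random.Generator`;
identical seeds give byte-identical JSON reports.  ZTP fitting uses Brent
root-finding at tolerance 1e−12 with the boundary (all counts = 1)
flagged; ZTNB uses L-BFGS-B within |log θ| ≤ 20.  Probabilities are
accumulated in log space (`gammaln`, `log1p`, `expm1`).  Degenerate
inputs return NaN with warnings rather than raising (constant Mantel
matrices, monomorphic-everywhere G_IS/R_ST, H_S = 1, fewer than three
spatial classes); structural violations (duplicate coordinates, odd
allele columns, counts below one) raise.

Default problem sizes in the test-suite and acceptance script (for
example 20 replicate simulations for the equilibrium check, 500
likelihood-ratio replicates, 300 Mantel replicates at 199 permutations,
500–1,000 spatial permutations) were chosen as the smallest designs whose
Monte-Carlo error is well below the effect sizes being checked.

## Known limitations

Ploidy is fixed at 2; no polyploid distance variants.  The simulator has
no seed-dispersal kernel between patches, no tidal-gradient fitness
differences, and no ramet mortality, so it cannot generate isolation by
distance or disturbance signatures.  The patch bootstrap bias for G''_ST
(above) is inherited from the resampling design.  The Bayesian
null-allele/inbreeding mixture models sometimes applied to such data are
out of scope; homozygote-excess diagnostics here rest on G_IS and the
simulator's explicit null-allele mechanism.
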