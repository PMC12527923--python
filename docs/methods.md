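# Methods

This note documents the models and procedures implemented in `timbertrace`,
the assumptions behind the synthetic-data generator, the tunable parameters
that matter, and the numerical choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

A reference database holds, for a set of geolocated sites, per-tree
measurements from up to three forensic methods: haploid biallelic SNP calls
from the plastid genome (SNP), stable-isotope ratios δ¹⁸O, δ²H and δ³⁴S in ‰
(ISO), and concentrations of ~41 elements in g/kg (EL). Two questions are
asked of a wood sample: *identification* — which reference site is its most
likely origin? — and *verification* — is a claimed origin consistent with its
measurements? Site locations are the centroids (arithmetic mean lat/lon) of
their trees' GPS coordinates, and all site-to-site distances are great-circle
(haversine, R = 6371 km) distances between centroids. The haversine choice is
a design decision; at the sub-1000 km scale of interest it differs from any
reasonable projected metric by far less than a distance bin.

## Preprocessing

* **Genetic missingness filter.** Individuals with strictly more than 50%
  missing calls are removed first, then loci with strictly more than 25%
  missing calls among the remaining individuals. Both thresholds are strict
  inequalities (a tree at exactly 50% survives); applying the filter twice
  changes nothing.
* **Detection-limit exclusion.** An element reported below its detection
  limit in strictly more than 100 samples is dropped. Below-detection cells
  of retained elements are substituted at DL/2 — the standard left-censoring
  substitution; the substitution constant is a package choice, as is any.
* **SNP imputation.** A missing call becomes the most common allele among
  observed calls at the tree's site, ties resolving to the lowest allele
  code (deterministic and auditable). Where a site has no observed call at a
  locus, the global mode is used. Modes can be restricted to a caller-chosen
  subset of trees; the identification experiment passes the training ids so
  no test measurement influences a training statistic.
* **Isotope imputation.** Missing isotope values become the site mean over
  measured trees — by default over measured *training* trees only. Test trees
  missing δ³⁴S therefore receive a site-labelled training statistic; this
  harmonization is how sparsely measured proxies are fused with dense ones in
  practice, and it is the one deliberate information channel from site
  identity into the feature table.
  Its consequence is measurable: on otherwise signal-free data with isotope
  missingness switched on, isotope-model accuracy rises above chance. For
  this reason the null-calibration experiments use a missingness-free world
  (see below).
* **Test-set selection.** Eligible trees have complete element and genetic
  data and measured δ²H and δ¹⁸O. A test set of ⌊fraction × pool⌋ trees
  (default 50%) is allocated across sites proportionally to their eligible
  counts with largest-remainder rounding, at least one tree per represented
  site where the budget allows; sites with no eligible trees are warned about
  and absent from the test set.

## Ordination

Genetic distances are 1 − proportion of shared alleles; for haploid data this
is the mismatch proportion over jointly observed loci (pairwise deletion). A
pair with no jointly observed locus is an error. Chemical tables use the
chord distance (Euclidean distance between rows scaled to unit norm), which
is scale-invariant per tree and bounded by √2 for non-negative orthogonal
profiles. Isotope tables contain negative ‰ values, for which the chord norm
has no compositional meaning; each isotope is therefore range-standardized to
[0, 1] first (a configuration switch), plus a uniform 10⁻⁶ shift so the tree
at the minimum of every variable does not degenerate to a zero vector.

db-RDA: the squared distance matrix is Gower-centred; principal-coordinate
axes with eigenvalues above 10⁻⁸ × the largest are retained (negative
eigenvalues are dropped, no Lingoes/Cailliez correction); the coordinates are
regressed on centred site indicators; pseudo-F is the ratio of constrained to
residual mean squares with (g−1, n−g) degrees of freedom; significance comes
from freely permuting rows, p = (1 + #{F* ≥ F}) / (1 + B) with B = 999 by
default. On fully Euclidean-embeddable distances this pseudo-F coincides
with the one-way PERMANOVA statistic, which the test suite verifies against
an independent implementation. Two numerical notes: (1) the permutation p is
granular in units of 1/(B+1); (2) with two *equal-sized*, fully separated
groups a permutation can recreate the identical partition by swapping the
labels wholesale, tying the observed F, so the minimal p of 1/(B+1) is only
structurally guaranteed for unequal group sizes — the calibration fixtures
use 10 + 9 observations for this reason.

## Identification experiment

For each of `n_repeats` (default 25) hold-out draws, the seven method-set
feature tables are built (SNP alleles as 0/1 columns, isotopes and elements
as numeric columns, prefixed and identically ordered for train and test), a
random forest is trained per method set, and every test tree is assigned to
the site with the highest mean vote, ties to the lexicographically smallest
label. Forests default to 500 trees with √p features per split, the standard
classification defaults; training is deterministic given the seed.
Accuracy is the % of correct assignments; its SD is taken across the repeat-
level accuracies. Distances from true to predicted site centroid are binned
as {exact, (0,50], (50,100], (100,300], (300,500], (500,1000], >1000 km};
the bin edges are configurable with these defaults since the reading points,
not the exact edges, are what the summary communicates. The RDM baseline
assigns every tree to the site of every reference tree (so candidate sites
are weighted by reference counts; a uniform-weight variant exists) and bins
the resulting distances — the expected outcome of fully random assignment.

## Verification experiment

The same randomly drawn test subset (default 41 trees) is evaluated under
both scenarios for every method set. Scenario A trains on all trees except
the focal one and confirms the (true) claim iff the prediction equals it.
Scenario B draws a false claim uniformly from the other sites, removes every
tree of the focal tree's *true* site from training — the true origin is
unknown and absent from the reference — and rejects the claim iff the
prediction differs from it; the true origin can never be predicted because it
is absent from the label set (asserted on every outcome). If only one site
remains in training, the assignment is forced to it without fitting.
Imputation statistics are recomputed from each verification model's own
training set. Chance baselines for K sites: 100/K confirmed, and
100·(K−2)/(K−1) rejected (the true origin is removed, leaving K−1 candidates
of which K−2 differ from the claim), reported to one decimal.

## Synthetic-data generator

The generator produces worlds with the statistical structure the analysis
assumes, not a mechanistic simulation: no coalescent model, no isotope
fractionation physics, no soil-chemistry model. Defaults emulate the study
design the pipeline was built for.

* **Geometry.** 13 sites placed by rejection sampling in a ~1100 km box
  (Central-African coordinates, WGS84), at least 15 km apart; 15–20 trees per
  site scattered within 5 km of the site centre; site locations recomputed as
  tree-coordinate centroids. Site labels follow a country/number scheme
  (CAM/GAB/CON) for familiarity.
* **Genetics** (238 loci). Sites are partitioned into 3 spatially contiguous
  clusters by a 1-D split on longitude — contiguity mimics refugial
  structure; the generative model is the package's own choice. Per-locus
  cluster allele frequencies follow a Balding–Nichols-style draw around an
  ancestral frequency with divergence F = 0.30. Within clusters, site-level
  logit shifts are drawn from an exponential spatial covariance (e-folding
  300 km, SD 0.45) and shared across consecutive 8-locus blocks — loci on the
  non-recombining plastid genome travel together, which the block structure
  imitates cheaply. F = 1 is special-cased to alternating fixed alleles so
  that fully diverged clusters are exactly one PSA unit apart.
* **Isotopes.** Site means lie on a random-direction linear gradient plus
  smooth low-frequency spatial noise, affinely scaled so the means span 60%
  of the observed ‰ ranges (δ¹⁸O 24.7–30.4, δ²H −9.5–36.55, δ³⁴S 4.6–10.9);
  tree values add Gaussian noise whose default SD equals the SD of the site
  means — the weak-signal regime in which local variation rivals across-site
  variation.
* **Elements.** 41 elements named after the measured panel, with log-spaced
  baseline medians from 4.0 (K) down to 0.001 (Yb) g/kg and log-normal tree
  noise (σ = 0.4). Five elements (W, Ba, Mo, K, Cr) carry independent
  per-site multiplicative offsets (σ = 0.8 in log space) — a fine-scale soil
  mosaic deliberately uncorrelated with the genetic clusters, which is what
  makes the methods complementary. An option restricts the offsets to sites
  of a single genetic cluster for the strict-complementarity experiments.
* **Missingness.** SNP cells are masked independently (default 5%). Isotope
  masking operates per (site, isotope): each site keeps a nested random
  subset of measured trees — 6–10 for δ¹⁸O, 4–10 for δ²H, 2–4 for δ³⁴S — so
  trees measured for the scarcest isotope are measured for all. A
  configuration that would leave a site with zero complete trees is an error.
* **Seeding.** One global seed fans out into named substreams (sites,
  genetics, isotopes, elements, missingness), so each proxy is independently
  reproducible; the config and seed are stored in the dataset's provenance.

The two free divergence scales (genetic site-shift SD, element site-offset
SD) were calibrated once so that single-method identification accuracies on
the default design fall in the realistic 40–75% band, and frozen; they are
documentation of a plausible world, not ground truth. What passing tests on
these worlds demonstrate is that the *pipeline* behaves correctly — at chance
on signal-free data, above every single method when signals are
complementary — not that any particular field accuracy will be attained:
real data add cryptic population structure, laboratory batch effects,
measurement error correlated within sites, and reference gaps that the
generator does not emulate.

## Null calibration and problem sizes

Chance-level checks (identification at 1/13, scenario-B rejection at 11/12)
run on a signal-free world with *no* missingness, because the site-mean
isotope imputation is an intentional site-information channel that lifts
isotope-model accuracy above chance whenever imputation fires (see
Preprocessing); with no missing cells no imputation occurs and every feature
is exchangeable across sites. Experiments in the test suite and acceptance
script use 6 hold-out repeats, 150-tree forests for calibration runs (the
null argmax distribution is insensitive to forest size), 10 replicate worlds
for the complementarity experiment, and 200 simulated datasets for the
permutation-test calibration — sizes chosen to give useful Monte-Carlo
resolution (≥500 pooled assignments per rate, binomial SE ≲ 1.3 pp) at
desk scale.

## Known limitations

* Verification is argmax-based: no likelihood ratios or court-calibrated
  error rates.
* No probabilistic origin surfaces (isoscape-style continuous assignment);
  outputs are site-level.
* The db-RDA drops negative eigenvalues rather than correcting them; for
  strongly non-Euclidean distances the constrained-variance proportions are
  approximate (the permutation test itself remains exact under
  exchangeability).
* The generator's plastid "blocks" capture within-genome correlation only
  coarsely, and element detection limits are set low enough that the default
  worlds contain essentially no censoring; censoring behaviour is exercised
  through fixtures instead.
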