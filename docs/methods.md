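# Methods

This note records the models behind each pipeline stage, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the procedure admitted more than one
reading.

## Sequence distances and the GD_min crosstable

K2P distances use pairwise deletion: each pair is compared only at columns
where both characters are unambiguous bases. IUPAC ambiguity codes are
treated as missing rather than fractionally matched — phased haplotypes
should be unambiguous, so residual ambiguity indicates upstream phasing
noise, not half a match. Saturated pairs (log argument ≤ 0) are flagged NaN
and skipped, with a warning, in every downstream minimum; they are never
silently dropped.

The crosstable reports, per pair of specimen units, 100 × the minimum
pairwise distance between their members. Banding compares GD_min against a
sister-species calibration: mean 3.98% with 95% CI [3.36, 4.59] (percent
per site), deflated by a factor 0.80 because an observed minimum sits below
a between-species average — "about 20% lower" is the only guidance the
calibration offers, so the factor and the inclusive window endpoints are
config (`GdBandConfig`). Below the deflated window → intraspecific, inside
(inclusive) → sister, above → interspecific. The conservative species count
single-links units across intraspecific bands and counts components;
hybrid-coded units are excluded by default (a named hybrid is not an extra
species). Rounding for display is half-even to one decimal.

## Haploweb

Identical sequences (p-distance 0 under pairwise deletion) collapse into
one node. The display network is a minimum spanning network (Kruskal by
mutation-step weight classes, all ties kept). Fields for recombination are
the connected components over **co-occurrence edges only** — mutational
adjacency does not imply a shared gene pool, so network edges never merge
FFRs. A haplotype never seen in a heterozygote is its own FFR; over-counting
relative to the species number is therefore expected at moderate sampling
and mirrors real haplowebs.

## ABGD-lite

A deliberately simplified barcode-gap partitioner: find the smallest
observed distance above the prior intraspecific divergence P whose gap to
the next-smaller observed distance exceeds X·P (X = 1.5 by default),
single-link below it, recurse within groups. It omits the original
algorithm's slope-based gap ranking; the output is labeled accordingly and
is intended for bracketing a species-number range over a prior grid, where
the group count is non-increasing in P on clean data.

## Single-threshold GMYC

The tree (ultrametric within relative tolerance 1e-6; polytomies resolved
with zero-length branches under a warning) is scanned over candidates
indexed by the j oldest internal nodes being speciation events. Above the
threshold, branching follows a Yule process with rate λ_Y·n (the root event
is conditioned out); below it, each of the j+1 crossing lineages is an
independent coalescent with combined rate λ_C·Σ n_i(n_i−1)/2. Both rates
are profiled analytically (events / lineage-weighted time), giving the
block log-likelihood Σ log w_e + E log(E/W) − E.

Two numerical choices matter:

- **Threshold placement.** The switch time is identified only up to the
  open interval between the youngest speciation node and the oldest
  coalescent node. Ending the Yule block at the interval's lower end
  overpenalizes true splits with long stem branches (survival exposure with
  no events); ending it at the upper end is the profile supremum but makes
  the test anticonservative under the null. The block boundary is placed at
  the interval midpoint, which in calibration runs recovers the true
  species number in 93% of well-separated replicates while rejecting a
  true single-Yule null in 8.5% of replicates at α = 0.05.
- **Degenerate fit.** When no mixed candidate improves on the single-Yule
  null, the fit reports one entity, threshold at the root, and
  logL_alt = logL_null, so LR ≥ 0 always. A whole-tree single-coalescent
  alternative is *not* a candidate: its event weights count cross-species
  lineage pairs and systematically dominate the true mixed model, which
  would collapse every fit to one entity.

The LR is referred to χ² with 2 degrees of freedom; the "window of
speciation" collects candidate thresholds within 2 log-likelihood units of
the optimum.

## Double factorization

Distance matrices become coordinates by classical PCoA (Gower centering of
−½D², eigendecomposition, scores scaled by √λ; negative eigenvalues are
reported and dropped). Each marker block retains factors with eigenvalue
above the block mean (minimum two); retained scores are z-standardized,
concatenated, and re-factored on the correlation matrix (PCF). Eigenvector
signs are fixed by making the largest-magnitude loading positive, so plots
reproduce exactly. Whether the original analysis Gower-centered the
sequence-distance matrix or treated its columns as variables is not
recoverable from the text; Gower centering is implemented as the default
and the raw eigenvalue scale is therefore not comparable to published
values — cluster separations are.

Subcluster refinement runs Ward clustering within each base cluster on the
leading combined factors (eigenvalue above the mean). The split count
maximizes the mean silhouette with a parsimony rule (smallest k within 0.05
of the maximum), and a split must additionally beat the 90th percentile of
the best silhouette over 20 seeded Gaussian replicates with the cluster's
own covariance. The flat silhouette floor of 0.25 is kept as config, but it
cannot by itself distinguish structure from noise: Ward cuts of isotropic
Gaussian noise score ≈ 0.43 in two dimensions at n = 15–30.

## Constrained morphospace

Collinearity pruning is greedy: repeatedly take the worst remaining pair
with |r| > 0.8 and drop the member with the larger mean |r| to all other
survivors (ties drop the later column). Ward morphotypes are computed on
standardized variables and ranked by the first PCF-axis centroid so group
numbers are stable across record orders. Ordinal and binary variables are
treated as numeric throughout, consistent with Euclidean Ward and linear
DA on a mixed-type matrix.

Variable selection is a **grouped multinomial lasso**: multinomial
negative log-likelihood plus λ·Σ_j‖W_j‖₂ with one group per variable
across classes, solved by FISTA with warm starts along a data-driven λ path
(λ_max down two decades). A per-class L1 penalty cannot zero whole
variables — the union of class supports retains several noise variables at
any CV-chosen penalty — which is why the grouped form is used. Penalties
are scored by 5-fold cross-validated deviance of a **relaxed** fit: the
active set is refit with a mild ridge (removing the lasso shrinkage bias
that otherwise drags CV toward weak penalties and large supports).
Candidates are the CV-minimum and the strongest penalty within one standard
error; n_min is the smaller support.

DA solves the generalized eigenproblem B v = λ W v (B between-unit, W
pooled within-unit scatter), capped at min(units−1, variables) axes.
Wilks' Λ = Π 1/(1+λ_k) = det(W)/det(W+B); the p-value uses Bartlett's χ²
approximation, adequate at the sample sizes involved but not at p ≳ n
(where W needs its ridge jitter of 1e-8·trace/p and the statistic is
reported with a warning). The Stewart–Love index is computed by canonical
correlation (QR + SVD) between the first m DA axes and the first m factors
of the full-morphospace PCF: redundancy = Σ ρ_k²·(mean squared correlation
of the Y variables with the k-th Y variate), which with all pairs retained
equals the mean R² of regressing each Y variable on X. GLM-R² — "ranked
cohesion" — is operationalized as the OLS R² of axis-1 scores on the rank
of the unit's axis-1 mean used as a single ordinal regressor; the original
text does not formalize it, so this definition is the package's own and is
config-exposed.

Morphoclouds are centroid-linkage clusters of the first three DA axes, cut
at the silhouette-maximal k in [2, 12]; a weak-structure warning fires when
the best silhouette does not clear Gaussian-noise reference cuts.
Aberrance classification: a cloud is pure when ≥ 90% of members share one
genetic main cluster; majority members of pure clouds are consistent,
minority members aberrant — unless within 0.5 pooled within-cloud SDs of
the midpoint toward a cloud of their own cluster (borderline) or listed in
a user-supplied override (look-alike; in the source analysis this category
is an expert call and is not reproduced automatically). Members of impure
clouds are mixed. The purity threshold interacts with unit size: at ~15–30
accessions per cloud, a handful of cross-cluster accessions landing in one
cloud flips the whole cloud to mixed; the planted-truth calibration
therefore uses large units (150 per cluster).

## Synthetic data

The generator states one world and is bit-reproducible per seed (each stage
draws from a stream derived from the seed by a fixed offset):

- **Species tree**: Yule topology over K species; node heights are mapped
  affinely onto [0.5, 1]×`depth_between` (default 0.06 substitutions/site)
  so every species pair is genuinely diverged rather than mid-radiation —
  the "distinct species" regime the delimiters assume. Within each species,
  a Kingman coalescent over a small pool (default 4 haplotypes) at
  `depth_within` (default 0.002). The small pool makes individuals share
  haplotypes, as real populations do; without sharing no heterozygote
  co-occurrence graph can connect.
- **Sequences**: Jukes–Cantor from a uniform root, Poisson(branch × length)
  substitutions, length 690. The downstream estimator is K2P, so estimation
  runs under mild, realistic model misspecification.
- **Individuals**: 1 or 2 haplotypes from the species pool
  (heterozygosity 0.5 by default); hybrids draw one haplotype from each of
  two species. Hybrid morphology is the parental midpoint.
- **Bands**: each marker has a home species; presence probability 0.9
  inside, 0.1 outside; hybrids take the larger parental probability
  (dominant markers show a band if either genome carries it).
- **Morphology**: 59 continuous + 52 ordinal + 11 binary variables. Unit
  mean shifts (±`effect_size`/√2 per coordinate, default 3 within-unit SDs)
  are placed on an informative core of 12 variables spread across the
  blocks; the rest are noise, so variable selection has something to find.
  Ordinal cells are averages of two independent 5-level scorings
  (half-integer grid); binary cells threshold the latent at 0. Three
  continuous variables get |r| > 0.9 twins to exercise pruning.

What a green test establishes: the pipeline recovers *planted* structure in
a world with clean cluster separation, no recombination, no pseudogenes, no
missing data beyond what tests inject, and morphological units identical to
genetic species. It does not establish performance under introgression
gradients, chromatogram-level phasing error, or environment-driven
plasticity — none of which the generator emulates.

## Known limitations

- The GMYC implementation is single-threshold with fixed χ²(2) reference;
  no multiple-threshold variant, no bootstrap support on entities.
- ABGD-lite is a threshold-gap recursion, not the original slope-ranked
  algorithm; absolute group counts on real data will differ even when the
  bracketing range is comparable.
- PCoA axes from standardized inputs cannot reproduce raw published
  eigenvalues of count-scaled analyses; comparisons should be made at the
  level of cluster separations.
- Bartlett's approximation for Wilks' Λ degrades when the variable count
  approaches the sample count; the pipeline avoids this by fitting DA on
  the selected subset, but direct `fit_da` calls on wide matrices warn.
- The borderline/look-alike aberrance categories are config-driven
  operationalizations; the original categories are expert judgments and
  exact reproduction is not claimed.
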