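# Methods

## The inference chain

`phylosalt` analyses a two-salinity reciprocal-transplant community
experiment: intact soil communities from a freshwater and a saltwater site
are incubated in both sites, giving four origin × host treatments (FF, FS,
SF, SS) with replicate samples. The pipeline runs in five stages.

**1. Community preparation.** Taxa whose share of all reads is strictly
below `rare_fraction` (default 5 × 10⁻⁵, i.e. 0.005%) are removed;
the inequality is strict, so a taxon holding exactly the threshold share is
retained. Rarefaction to a common depth is multivariate-hypergeometric
subsampling (without replacement), used for diversity analyses when a
depth is configured. Presence/absence is collapsed per treatment by a
replicate-majority rule: a taxon is *present* iff it is detected (count ≥
`min_detection_count`, default 1) in strictly more than half of the
treatment's replicates. With five replicates this is the 3-of-5 rule; with
even replicate counts the strict form resolves ties to *absent*
deterministically. By default presence is computed on the filtered,
non-rarefied table — detection sensitivity should not be degraded for a
presence call, and rarefaction is scoped to the diversity statistics — but
`presence_on_rarefied` switches the source.

**2. Preference classification.** A taxon's salinity preference is a pure
function of its four presence bits: present in both controls (FF ∧ SS) →
*none*; FF ∧ SF ∧ ¬SS → *fresh*; SS ∧ FS ∧ ¬FF → *salt*; anything else →
*unclassified*. The *none* rule deliberately names only the two controls
(FS/SF free), a literal reading of the stated criterion. The explicit
*unclassified* label keeps totals conserved and auditable; the raw 4-bit
pattern is emitted with every label so any alternative rule can be
re-derived from the output. Membership, not abundance: taxa merely
enriched or depleted between salinities are not called.

**3. Phylogenetic signal.** For each preference group (tip set S on the
community tree) the pipeline computes Faith's PD (total branch length of
the minimal spanning subtree; `include_root` — the default, matching the
picante lineage of implementations — adds the path from that subtree to
the root) and MNTD (mean patristic distance from each tip to its nearest
other tip in S). The null model draws `null_runs` (default 999) tip sets
of size |S| uniformly from the full tip pool; the pool is *all* tips of
the pruned tree (classified plus unclassified), because the tree is
already restricted to the observed community. The two configurable null
names, `taxa_labels` and `pool_draw`, are synonyms here: for a single tip
set, shuffling tip labels and drawing equal-size sets from the pool induce
the same distribution, so one uniform-draw implementation backs both.
SES = (obs − null mean)/null SD, NTI = −SES(MNTD); rank p-values use the
(r + 1)/(runs + 1) permutation convention (never 0, resolution
1/(runs + 1)). A degenerate null (SD = 0, e.g. the group is the whole
pool) yields SES = NaN with an explanatory note, never a silent 0.

**4. Clade enrichment.** For each clade (taxonomic lineages mapped at
phylum level, with Proteobacteria resolved to classes), the observed
percentage of each preference is compared with the community-wide
expectation — the preference's share of the comparison universe, which
defaults to the three named categories (*fresh*, *salt*, *none*);
`universe="all"` adds unclassified taxa. A percentile bootstrap (default
6000 iterations, 95% CI) resamples the clade's members with replacement,
clade size preserved; tallying categories over such a resample is
distributionally identical to one multinomial draw over the observed
category fractions, which is how the resamples are generated. Verdicts
require strict non-overlap: *enriched* if the CI lower bound exceeds the
expectation, *depleted* if the upper bound is below it, otherwise
*indistinguishable*. No multiple-testing correction is applied across
clades; clades below `min_clade_size` (default 10) are flagged
low-confidence rather than suppressed. BCa intervals are not offered —
plain percentile intervals keep the procedure transparent and exactly
enumerable at small n.

**5. Composition–function coupling.** Weighted UniFrac between samples A
and B is Σ_b ℓ_b |p_A(b) − p_B(b)| over branches b, where p_X(b) is the
fraction of sample X's reads descending through b; the normalized variant
divides by Σ_b ℓ_b (p_A(b) + p_B(b)) and lies in [0, 1]. Raw is the
default (the variant used by the tooling era this pipeline mirrors).
Functional distance is Gower: per-variable range normalization, mean
absolute difference, pairwise-complete over missing values, zero-range
variables dropped with a warning; all variables weigh equally. The Mantel
statistic is the Pearson correlation of the strictly-lower-triangle
entries (Spearman optional); the null jointly permutes rows and columns
of one matrix, with a one-sided upper-tail rank p (+1 convention),
default 999 permutations.

## The synthetic-data generator

The generator emulates the 2 origins × 2 hosts × 5 replicates design with
known ground truth. Defaults (the study conditions): 200 taxa, 21,398
reads per sample, λ = 1.

* **Tree**: pure-birth (Yule) with binary splits; waiting times between
  splits with k lineages are Exp(k·birth_rate), and a final Exp(n·rate)
  stem interval precedes harvesting, so trees are ultrametric; depth is
  rescaled to 1.
* **Niche trait**: Brownian motion with Pagel's λ — tip covariance is λ
  times the shared-path covariance off the diagonal with variances kept,
  so λ = 0 gives independent tips and λ = 1 the full tree covariance.
  Thresholds at the standard-normal tertiles (±0.4307 on the standardized
  latent scale) cut the trait into *fresh* / *generalist* / *salt* true
  classes, so the three classes are equally likely a priori and
  generalists arise naturally as the middle of the niche axis.
* **Detection**: per-environment probabilities (0.95 for a specialist in
  its own salinity, 0.02 in the opposite one, 0.90 for generalists
  anywhere). Control treatments use the origin environment directly. In a
  transplant, a taxon is detectable if it persisted from the origin
  community — tolerating the host, or lingering as residual (relic) DNA
  with probability `carryover` (default 0.9) — or colonized from the host
  environment with efficiency `colonization` (default 0.8). Carryover
  models the dormancy/relic-DNA signal expected when intolerant taxa die
  after transplantation but their DNA remains detectable; colonization
  supplies the host-environment taxa that the *fresh*/*salt*
  classification rules require in the transplant treatments.
* **Counts**: occupied taxa receive lognormal(0, 1) relative abundances
  per sample; reads are one multinomial draw at the configured depth, so
  column sums are exact and low-abundance occupants can still escape
  detection — a realistic detection-limit artefact.
* **Function profiles**: each of the nine variables (named for the seven
  assayed enzymes plus CO₂ and CH₄) is the community-weighted mean of a
  per-taxon functional trait evolved by Brownian motion on the same tree,
  mixed with the standardized salinity-niche trait at weight 0.5, plus
  Gaussian noise scaled to the variable's signal SD. The construction is
  deliberate: for a BM trait w, E[(w'p_A − w'p_B)²] = Σ_b ℓ_b (p_A(b) −
  p_B(b))², the squared-difference analog of weighted UniFrac, so
  functional distances track phylogenetic beta diversity by construction
  and `function_noise_sd` dials the coupling from deterministic (0) to
  absent (≫1). Unstructured random loadings provably cannot deliver a
  strong coupling with only nine variables; phylogenetically conserved,
  niche-aligned traits can, and are the more faithful picture of enzyme
  repertoires.

What the generator does **not** emulate: sequencing error and chimeras,
compositional correlations among taxa beyond co-occupancy, overdispersed
(non-multinomial) depth noise, per-replicate environmental heterogeneity,
and taxonomic lineages (clade enrichment is tested on constructed
assignments instead). Passing tests therefore demonstrate the statistical
machinery and its calibration, not the field accuracy of preference calls
on real sequence data.

## Calibration experiments and problem sizes

The acceptance suite runs the chain at the default scale (200 taxa, 20
samples, depth 21,398): 500 λ = 0 replicates for the size of the SES-PD
test (rejection rate at α = 0.05, SES moments, Mantel-p uniformity on
decoupled function tables), 100 λ = 1 replicates for power, a 30-replicate
λ-sweep for NTI monotonicity, 50 replicates for classifier recovery, and
200 bootstrap runs for enrichment calibration. The acceptance script uses
200 calibration replicates and 20 recovery runs — sizes chosen so a full
run completes in well under a minute per block while keeping Monte-Carlo
error small relative to the asserted margins.

## Numerical choices and conventions

* ID matching is exact and case-sensitive everywhere; silent case-folding
  hides upstream errors. Missing branch lengths are an error by default
  (`missing_length="zero"` opts in), because silently defaulted lengths
  corrupt PD.
* All randomized stages derive independent streams from a single integer
  seed keyed by stage name (CRC-32 of the stage label into a
  `SeedSequence`), so pipelines are bit-reproducible and adding a stage
  never perturbs another stage's draws.
* Uniform k-subsets for the SES null are taken as the k smallest entries
  of a uniform random vector, which vectorizes across the null runs.
* Faith's PD uses an edge–tip incidence matrix: with root, an edge counts
  iff ≥1 selected tip descends through it; without root, iff the edge
  separates two selected tips (descendant count strictly between 0 and
  |S|).
* Bootstrap CIs use linear-interpolated quantiles of the resampled
  percentages; at tiny n this reproduces the inverse-CDF quantiles of the
  exact enumeration with overwhelming probability at 6000 iterations.
* Tree pruning uses shear-and-collapse, which preserves patristic
  distances among retained tips (asserted by test).

## Known limitations

* Exact p-value resolution is bounded by the configured run count
  (1/(runs + 1)); strongly clustered groups saturate at the permutation
  floor.
* The preference classifier is conservative by design: a generalist that
  is merely depleted (not absent) in one salinity is called *none*, and
  relic DNA can keep an intolerant taxon "present" after transplantation —
  both tendencies mirror the behaviour of presence-based calls on real
  libraries.
* Gower distance assumes equal variable weights; there is no option to
  weight enzyme and gas variables differently.
* The enrichment verdicts are marginal per clade × preference; across many
  clades some false verdicts are expected in the absence of a
  multiple-testing correction (intentionally mirrored from the analysis
  design this package reproduces).
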