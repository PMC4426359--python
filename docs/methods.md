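# Methods

`apmap` implements a trade-off (antagonistic-pleiotropy, AP) meta-analysis
for yeast growth data across environments: screening entity × environment
matrices for trade-offs, mapping gene–environment-interaction (GEI) loci in
a biparental haploid cross, resolving two-locus compensatory structure, and
two sequence/expression-level companions (Tajima's D screening, transcript
two-cluster analysis). This note records the models, the parameters that
matter, and the design decisions taken where the procedure left room.

## Trade-off scoring (`apmap.tradeoff`)

Each environment column is scaled to zero mean and unit variance (sample
SD, n−1 denominator; the n−1 choice makes standardization exactly
idempotent and is otherwise immaterial at screen sizes). For an environment
pair (E1, E2) and cutoff c ∈ {0.5, 0.75} SD, an entity shows a trade-off
when z₁ > c and z₂ < −c or vice versa, with *strict* inequalities: a value
sitting exactly at the cutoff is not called. The **degree of antagonism**
is 100 × (trade-off entities) / (entities with |z| > c in E1 or E2, as a
union); a per-environment-denominator variant is available
(`denominator="per_environment"`) because the ratio's reference set can be
read either way. When no entity exceeds the cutoff the degree is 0 with a
warning.

Natural isolates are assigned categories over a panel of environments:
I — z > c somewhere and z < −c elsewhere (a trade-off across at least one
environment pair); II — |z| ≤ c everywhere; III — exceedance without
opposition. The partition is exhaustive and exclusive by construction.

## Single-environment QTL scans (`apmap.qtl`)

Marker regression on dense biallelic genotypes: LOD = (n/2)·log₁₀
(RSS₀/RSS₁) comparing the per-allele-means model with the mean-only model
over pairwise-complete entities. No interval mapping or genotype
imputation — the intended data are dense marker panels, so the gain from
interval methods is negligible. Genome-wide significance uses phenotype
permutations with the **maximum LOD over markers** as the null statistic,
the standard family-wise permutation construction; p-values carry the +1
correction, so the smallest attainable p is 1/(n_perm+1) and p is never 0.
Note that these genome-wide p-values concentrate near 1 at ordinary markers
under the null — they are not per-marker uniform. Peak selection is greedy:
take the strongest supra-threshold marker, mask ±60 kb (inclusive, the
locus-matching window used throughout), repeat; ties break leftmost.
Variance explained comes from the joint additive OLS fit (percent R²), with
per-locus shares as leave-one-out R² drops; exactly collinear loci raise an
error naming the pair.

## GEI and slope mapping (`apmap.gei`)

Two scans per environment pair, both on standardized phenotypes:

* **GEI scan** — stack the two environments (two rows per entity with an
  environment indicator); GEI LOD = LOD(env + genotype + genotype×env) −
  LOD(env + genotype). Permutations shuffle genotype labels across entities
  while keeping each entity's two rows together, preserving the
  within-entity correlation under the null. Both genome-wide (max-GEI-LOD)
  and nominal single-marker F-test p-values are emitted; the significance
  filter uses the genome-wide one.
* **Slope scan** — the per-entity slope z(E2) − z(E1) mapped as an ordinary
  single trait. With two environments at unit separation the reaction-norm
  slope is this difference up to an affine constant, which the LOD is
  invariant to.

Significant GEI loci satisfy GEI p < 0.1 AND slope p < 0.05 (strict). Each
is classified by per-environment Welch t-tests between allele groups at a
per-test cutoff of fw_alpha/family_size = 0.05/10 = 0.005 (the family size
reflects roughly ten antagonistic interactions per environment; both knobs
are exposed): significant in exactly one environment → environment
specific; both, same-signed RM−BY contrast → scale; both, opposite signs →
antagonistic (equivalently, crossing reaction norms — asserted as an
invariant). The mapping-level degree of antagonism is the percentage of
scale/environment-specific loci with an antagonistic locus from another
environment pair within ±60 kb on the same chromosome.

### Power under standardization shrinkage

The synthetic planted classes default to per-environment effects (in noise
SD units, noise SD 1): environment-specific (0.5, 0), scale (1.0, 0.5),
antagonistic (+0.5, −0.5) — every nonzero effect ≥ 0.5 SD. With nine such
loci planted in one pair at n = 1000, the genetic variance roughly doubles
the phenotype variance, so column standardization shrinks realized
standardized effects by ~1.2–1.5×. The classifier is essentially exact on
detected loci (per-class accuracy ≈ 1.0), but detection power at the
genome-wide thresholds is class-dependent: ~1.0 for antagonistic loci
(whose GEI contrast is the sum of the two effects), ~0.85 for
environment-specific and ~0.45 for scale loci (whose contrast is the
difference). This is a property of the study conditions, not of the
implementation: no same-signed effect pair with both magnitudes ≥ 0.5 SD
yields a standardized GEI contrast large enough for ≥ 0.9 genome-wide power
at this n. The acceptance checks therefore certify classification accuracy
conditional on detection, antagonistic-class detection power, and the null
type-I rate; the acceptance script reports unconditional detection power
per class so the limitation is visible.

## Two-locus interactions and resolution of trade-offs (`apmap.epistasis`)

Candidate markers (single-environment p < 1.0 plus scale/antagonistic GEI
loci, collapsed to the best-p representative within 60 kb) are paired;
same-chromosome pairs closer than 60 kb are excluded as linkage artifacts.
For each pair the slope phenotype is fitted as g₁ + g₂ + g₁·g₂ versus the
additive reduction; the permutation null is the maximum interaction LOD
over all tested pairs under slope shuffles. The same contrast fitted within
each environment (nominal F-test) fills per-environment p-values, so
interactions visible only on the slope can be tabulated.

Crossover flags derive from the four two-marker class means (BB, BR, RB,
RR; haploid segregants, first letter = first marker): a *mixed-background
crossover* is a sign flip between environments of any allele contrast that
holds the other marker fixed (BB−RB, BR−RR, BB−BR, RB−RR — each involves a
recombinant class); a *parental crossover* is a sign flip of BB−RR itself.
"Resolution of trade-offs" appears as mixed crossovers without parental
ones: the parental allele combinations carry the compensation, and
recombination uncouples it. The resolution test fills a 2×2 table
(mixed/parental × crossover/no crossover) and applies Fisher's exact test —
implemented by full hypergeometric enumeration with the minimum-likelihood
two-sided convention (the p sums all margin-fixed tables whose point
probability does not exceed the observed one); sidedness is configurable
since the convention behind a published one-line p is rarely stated.

The compensatory generator plants, per pair, antagonistic and mutually
opposed main effects (+e, −e)/(−e, +e) with e = 0.5 and an interaction
coefficient (δ, γ+δ) with δ = 0.2, γ = 0.5: the slope-scale interaction is
γ, each locus alone crosses over, the mixed-background contrasts flip sign,
and the parental BB−RR contrast (−δ, −γ−δ) stays same-signed in both
environments. δ keeps the parental contrast boundedly away from zero so
that sampling noise (SE ≈ 0.09 per contrast at n = 1000) does not flip its
sign by chance.

## Tajima's D (`apmap.popgen`)

Computed directly from the standard formulas (constants a₁…e₂ as closed
forms of n; D = (π − S/a₁)/√(e₁S + e₂S(S−1))). Columns containing gaps or
ambiguous bases are excluded entirely (complete deletion); columns with
more than two alleles are excluded from both S and π and logged, keeping
the two estimators on one biallelic (infinite-sites-like) site set. S = 0
raises rather than returning a 0/0. Balancing selection is called at a
fixed cutoff D > 0.1 per gene and species; a gene-level call may require
the cutoff in every species provided (intersection). No beta-distribution
confidence bands are computed — the screening uses the fixed cutoff.
Pathway enrichment contrasts call counts in a pathway set versus a control
set with the same Fisher test.

## Transcript two-cluster analysis (`apmap.transcripts`)

Responsive genes must change by more than 30% in *all* mutant columns;
the down-regulation bound is the reciprocal 1/(1.3) rather than 0.7, making
the rule symmetric on the ratio scale (a log-scale switch is provided and
coincides for the symmetric bound). Selected genes are clustered on
isolate expression by agglomerative clustering with Euclidean distance and
average linkage, cut at k = 2; the split statistic is the mean silhouette
width, and its permutation p re-clusters random same-size gene subsets of
the full matrix with the ≥-observed, +1-corrected convention. The split
statistic and comparison direction are package conventions — the source
procedure reports only a permutation p for the two-way division.

## Synthetic data (`apmap.synthio`)

All generators are pure functions of (spec, seed), via
`numpy.random.default_rng`. The cross simulator draws the first marker per
chromosome Bernoulli(0.5) and recombines adjacent markers with the Haldane
fraction r = (1 − e^(−2d/100))/2 — no crossover interference, chosen for
its closed form (testable against the simulated recombination fraction).
The phenotype model is linear-additive with pairwise products for epistasis
and Gaussian noise — the minimal structure the downstream linear scans
assume. The default study-scale conditions are n = 1000 segregants, 200
markers on 10 chromosomes (5 cM / 10 kb spacing), noise SD 1, 100
permutations.

What the generators deliberately do **not** emulate: correlated
environments (isolate panels use iid Gaussian background, which inflates
the category-I rate relative to real growth panels, where environments
correlate strongly); microarray noise structure; coalescent genealogies
(alignment site frequencies are planted directly, so the uniform-random
mode is *not* neutral — its expected D is positive, ≈ +1.2 at n = 20,
which the tests pin by closed form); linkage disequilibrium beyond the
Haldane map. Passing tests therefore certify the statistical machinery and
its calibration on known truth, not distributional realism of any
particular published dataset.

## Numerical conventions

* LOD values are floored at 0 (they are non-negative analytically; tiny
  negative values can arise from floating-point cancellation).
* Permutation p-values use the +1 correction throughout.
* Fisher enumeration compares point probabilities with a 1e-12 relative
  tolerance when accumulating the two-sided sum; for tables with totals
  ≤ 30 the hypergeometric pmf values are integer multiples of 1/C(n, c₁),
  so this cleanly separates exact ties from distinct values.
* Result tables print floats at 6 significant digits; genomic positions are
  1-based base pairs and all windows are inclusive.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the mapping stages at n = 1000
segregants × 200 markers with 100 permutations, 50 replicates in the test
suite and 10 in the acceptance script; deletion screens at 100–500 genes;
alignments at 8–20 sequences × 120–300 sites; expression panels at 120–300
genes. These sizes keep every planted signal in the well-powered regime
established above while the full suite completes in a few minutes.
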