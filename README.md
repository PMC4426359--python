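# apmap — antagonistic-pleiotropy mapping toolkit

`apmap` is a Python toolkit for finding and dissecting **antagonistic
pleiotropy (AP)** — genes or alleles that improve growth in one environment
while worsening it in another — in yeast-style growth data. It is aimed at
quantitative geneticists working with three kinds of input:

* **entity × environment growth screens** (deletion collections, natural
  isolate panels),
* **biparental segregant panels** (genotypes + multi-environment growth),
* **sequence alignments and expression panels** for follow-up
  (balancing-selection screening, pathway-target clustering).

## What it computes

**Trade-off scoring.** Growth values are standardized per environment
(zero mean, unit variance); an entity shows a trade-off between E1 and E2
when z₁ > c and z₂ < −c or vice versa (strict, c = 0.5 or 0.75 SD). The
*degree of antagonism* is the percentage of trade-off entities among all
entities exceeding the cutoff in either environment. Isolates are
categorized: I — trade-off across some environment pair; II — within ±c
everywhere; III — exceedance without opposition.

**GEI / slope QTL mapping.** For an environment pair, two scans on
standardized phenotypes: a gene–environment-interaction scan
(environment-as-covariate; GEI LOD = LOD(G + E + G×E) − LOD(G + E), with
genotype-label permutations) and a slope scan (z(E2) − z(E1) mapped as a
single trait, phenotype permutations; both use genome-wide max-LOD nulls).
Loci with GEI p < 0.1 and slope p < 0.05 are classified by per-environment
Welch t-tests at α = 0.05/10 = 0.005 into **environment-specific**, **scale**
(same direction, different magnitude) or **antagonistic** (opposite
directions — crossing reaction norms).

**Two-locus resolution of trade-offs.** Candidate marker pairs are tested
for an interaction on the slope phenotype (g₁ + g₂ + g₁·g₂ vs additive,
max-over-pairs permutation null). From the four two-marker class means
(BB/BR/RB/RR per environment), crossovers are counted separately for
recombinant (mixed) and parental allele combinations; an excess of mixed
crossovers — parental combinations staying parallel — is the signature of
compensated (resolved) trade-offs, tested with Fisher's exact test
(exact hypergeometric enumeration).

**Balancing selection.** Tajima's D per aligned gene
(D = (π − S/a₁)/√(e₁S + e₂S(S−1)), complete deletion of gapped columns),
calls at D > 0.1, optional per-species intersection, and Fisher-based
pathway-vs-control enrichment.

**Transcript two-cluster analysis.** Genes changed > 30% in all pathway
mutants, clustered on isolate expression (Euclidean, average linkage,
k = 2); split strength = mean silhouette, significance by re-clustering
random same-size gene subsets.

A fully tested synthetic-data module (`apmap.synthio`) generates every
input class with planted ground truth — a Haldane-map biparental cross,
phenotypes with planted QTL of the three GEI classes and compensatory
epistatic pairs, deletion screens, isolate panels, alignments with tunable
site-frequency spectra, and expression panels.

## Worked example

```python
from apmap import synthio, tradeoff, gei

mm = synthio.grid_marker_map()                      # 10 chromosomes x 20 markers
cross = synthio.simulate_cross(1000, mm, seed=7)
truth = synthio.planted_truth(mm, ["YPD", "H2O2"], seed=8)
pheno, _ = synthio.simulate_phenotypes(cross, truth, ["YPD", "H2O2"])
z = tradeoff.standardize_columns(pheno)

records = gei.map_gei_pair(cross, z, ("YPD", "H2O2"), n_perm=100, seed=9)
planted = {q.marker_id: q.gei_class for q in truth.qtls}
for rec in records:
    if rec.marker_id in planted:
        print(f"{rec.marker_id}  p_gei={rec.p_gei:.3f}  p_slope={rec.p_slope:.3f}  "
              f"class={rec.gei_class}  (planted: {planted[rec.marker_id]})")
```

prints

```
chr01_m010  p_gei=0.010  p_slope=0.010  class=env_specific  (planted: env_specific)
chr02_m010  p_gei=0.020  p_slope=0.010  class=env_specific  (planted: env_specific)
chr03_m010  p_gei=0.020  p_slope=0.010  class=env_specific  (planted: env_specific)
chr05_m010  p_gei=0.020  p_slope=0.010  class=scale  (planted: scale)
chr07_m010  p_gei=0.010  p_slope=0.010  class=antagonistic  (planted: antagonistic)
chr08_m010  p_gei=0.010  p_slope=0.010  class=antagonistic  (planted: antagonistic)
chr09_m010  p_gei=0.010  p_slope=0.010  class=antagonistic  (planted: antagonistic)
```

Nine loci were planted (three per class). Every planted locus that passes
the joint GEI/slope filter (here 7 of 9; two weaker same-direction loci
fall below the genome-wide slope threshold in this replicate) receives its
planted class: p-values of 0.010 are the smallest attainable with 100
permutations, and the three antagonistic loci are the crossing-reaction-norm
trade-off alleles the pipeline is built to find.

The same stages are available from the shell via the `apmap` CLI
(`simulate`, `apscore`, `scan`, `gei`, `twoqtl`, `tajima`, `cluster`);
see `apmap --help`.

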