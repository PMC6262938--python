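# palmflow

Genetic-diversity, spatial-genetic-structure, parentage and dispersal
analysis for mapped microsatellite samples of plant populations.

`palmflow` is aimed at population geneticists working on gene flow and
mating patterns in continuous stands of outcrossing plants — the classic
setting of a few dozen mapped reproductive adults surrounded by their
regenerated offspring, all genotyped at codominant SSR loci. It bundles, in
one tested pipeline:

- **Diversity and inbreeding** per ontogenetic stage: allele counts *k* and
  means *A*, rarefied allelic richness *A*<sub>r</sub>, private alleles
  *A*<sub>p</sub>, observed and Nei-unbiased expected heterozygosity
  *H*<sub>o</sub>, *H*<sub>E</sub>, and the fixation index
  *F* = 1 − *H*<sub>o</sub>/*H*<sub>E</sub> with a Monte Carlo allele-permutation
  test and Bonferroni correction.
- **Spatial genetic structure (SGS)**: pairwise Loiselle coancestry
  θ<sub>ij</sub> relative to sample allele frequencies, correlograms over ten
  equal-frequency distance classes with 95% permutation envelopes, the
  regression slope *b*<sub>k</sub> of θ<sub>ij</sub> on ln *d*<sub>ij</sub> with
  a coordinate-permutation test, and the comparative intensity statistic
  *Sp* = −*b*<sub>k</sub>/(1 − θ<sub>1</sub>).
- **Effective size** from group coancestry,
  Θ = [0.5 *n*(1 + *F*) + ΣΣ<sub>j≠i</sub> θ<sub>ij</sub>]/*n*², with
  *N*<sub>e</sub> = 0.5/Θ.
- **Categorical parentage**: error-tolerant CERVUS-style LOD scores over all
  candidate parent-pairs (selfing included), acceptance by the Δ (LOD-gap)
  criterion calibrated by simulation at a stated confidence, parent-pair
  exclusion probability *P*<sub>p</sub>, gene-flow rates (selfing *s*, pollen
  immigration *m*<sub>p</sub>, seed immigration), pollen/seed dispersal
  distances, the effective pollination neighborhood
  *A*<sub>ep</sub> = 2πσ<sub>p</sub>², and a Kolmogorov–Smirnov comparison of
  pollen distances with the intermate-distance distribution.
- **Neighborhood mating model**: spatially explicit maximum-likelihood
  decomposition of each offspring into selfing (*s*), pollen immigration
  (*m*<sub>p</sub>) and kernel-weighted within-plot siring, with an
  exponential-power dispersal kernel
  *p*(*r*) = *b*/(2π*a*²Γ(2/*b*)) · exp(−(*r*/*a*)<sup>*b*</sup>) and mean
  dispersal distance δ = *a*Γ(3/*b*)/Γ(2/*b*).
- **A forward simulator** of mapped SSR populations with known pedigree and
  mating parameters, so every estimator can be validated against ground
  truth without field data.

## Worked example

Simulate a study-like stand (10 ha, 59 reproductive adults, 189 offspring,
18 SSR loci, selfing 4%, pollen immigration 40%) and analyse it:

```python
from palmflow import (SimulationConfig, simulate_population, ParentageModel,
                      assign_parentage, dispersal_summaries)
from palmflow.sgs import analyze_stage_sgs

cfg = SimulationConfig(seed=42)
data, truth = simulate_population(cfg)

assignments, flow = assign_parentage(data, ParentageModel(n_sim=2000), seed=42)
disp = dispersal_summaries(assignments, data)
corr, sgs = analyze_stage_sgs(data, "seedling", n_perm=1000, seed=42)
```

which prints, via the obvious f-strings:

```
offspring analysed      : 189
selfing rate s          : 4.2%  (simulated truth 4.0%)
pollen immigration mp   : 39.7%  (simulated truth 40.0%)
mean pollen distance    : 132.9 m
pollination area Aep    : 1.64 ha
seedling theta_1        : 0.0140
seedling bk             : -0.00437 (p = 0.072)
seedling Sp             : 0.0044
```

The parentage machinery recovers the generating selfing and immigration
rates to within a fraction of a percent; θ<sub>1</sub> > 0 and
*b*<sub>k</sub> < 0 in the seedling stage reflect the short-distance seed
kernel (mean 60 m) used by the generator, and *Sp* puts that structure on
the scale used to compare studies.

The same analyses run from the shell: `palmflow simulate`, `palmflow
diversity`, `palmflow sgs`, `palmflow ne`, `palmflow parentage`,
`palmflow nm`, or end-to-end with `palmflow run --config analysis.yaml`.

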