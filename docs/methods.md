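# Methods

This note records the statistical procedures implemented in `palmflow`, the
defaults they ship with, and the choices made where several defensible
conventions exist.

## Data model

A sample is a set of individually mapped plants with an ontogenetic stage
label and a diploid genotype (unordered allele-code pair, or missing) at
each SSR locus. Allele codes are opaque positive integers; no binning is
performed. Coordinates are planar meters; a helper projects GPS lon/lat by
a local equirectangular projection about the plot centroid, whose error is
negligible at the few-tens-of-hectares extents this package targets.
Reference allele frequencies are always tallied from non-missing calls of
the group under analysis (each stage is analysed independently), except in
parentage, where the whole sample is the reference pool. An explicit
exclusion list (`GenotypeDataset.drop_ids`) supports reproducing analyses
that removed individuals for reasons external to the data.

## Diversity and inbreeding

- Expected heterozygosity uses Nei's unbiased estimator
  (2n/(2n−1))(1 − Σp²); this matches the convention of the common R
  toolchain for SSR diversity tables.
- Allelic richness is hypergeometric rarefaction to a common gene count g:
  Ar = Σ_a [1 − C(2N−N_a, g)/C(2N, g)]; with g equal to the full gene count
  it reduces to the raw allele count, and it is non-decreasing in g. The
  pipeline default g is the minimum per-locus gene count across stages.
- The multilocus fixation index is the ratio of summed heterozygote
  deficits to summed HE over loci (not the mean of per-locus ratios), which
  weights loci by information and is robust to near-monomorphic loci
  (HE = 0 loci are excluded with a record).
- The F test shuffles the 2n allele copies among individuals within each
  locus independently — the Hardy-Weinberg null — and the two-sided p-value
  counts permuted |F*| ≥ |F| with the observed statistic included
  (p = (b+1)/(B+1)). Bonferroni correction is applied across the stage-level
  multilocus tests; per-locus tests are reported unadjusted. Default 1,000
  permutations, default seed 20140000, always logged.

## Spatial genetic structure

Pairwise coancestry follows the Loiselle estimator with the small-sample
bias term w_l/(n_l−1) added per locus and the multilocus value as the
polymorphism-weighted (w_l = Σ p(1−p)) ratio of sums; monomorphic loci have
zero weight and drop out, and a pair's missing locus is skipped for that
pair only. Because the estimator is centred on sample frequencies, the
all-pairs mean is slightly negative, of order 1/n.

Distance classes are equal-frequency (deciles of the pairwise-distance
distribution by default); ties on a boundary fall to the lower class, and
duplicate quantile bounds collapse with a warning. The correlogram
envelope and the b_k test both permute individual spatial positions
against genotypes (10,000 permutations by default): per class the 2.5/97.5
percentiles of permuted means form the 95% envelope; for the slope, the
p-value counts |b_k*| ≥ |b_k|. b_k is the least-squares slope of θ_ij on
ln d_ij over all individual pairs (not class means), matching the
definition under which Sp = −b_k/(1−θ_1) is comparable across studies;
zero-distance pairs are excluded from the regression with a warning. The
Sp identity holds to machine precision by construction, and tests verify
the permutation tests achieve their nominal type-I error on null
simulations.

## Group coancestry and effective size

Θ = [0.5 n (1+F) + Σ_i Σ_{j≠i} θ_ij]/n², with the double sum over ordered
pairs so that the unrelated, non-inbred case reduces exactly to 1/(2n) and
Ne = 0.5/Θ = n. Negative F estimates are floored at zero before use, and
the F fed in is the same multilocus fixation index computed for that stage.
A non-positive Θ (possible under strongly negative coancestry sums) yields
an undefined Ne with a diagnostic rather than a negative size.

## Categorical parentage

Likelihoods follow the categorical maximum-likelihood framework with
genotyping error: per locus, L = (1−E)·T₀ + E·P(g_o), where T₀ is the
Mendelian transition probability of the offspring genotype given the
parent genotypes (pair, single-parent, or self-pair), P(g_o) the
Hardy-Weinberg unrelated likelihood, and E = 1−(1−e)^k with k the number of
error-prone genotypes in the configuration (3 for a pair, 2 for a single
parent or a self-pair). This single-replacement approximation matches the
class-I error model (random HWE replacement at rate e) that the simulator
uses, and avoids a three-way marginalisation that changes LODs negligibly
at the default e = 0.01. Candidates missing a locus contribute the
single-parent (or unrelated) term there; with e = 0 a Mendelian
impossibility gives LOD = −∞ and counts as a mismatch.

The Δ criterion is calibrated by simulation (default 10,000 replicates):
mothers are drawn uniformly from the candidate set; with probability equal
to the assumed sampled fraction of pollen donors (default 0.5) the father
is also a candidate (possibly the mother, i.e. selfing), otherwise an
unsampled HWE individual. Each simulated offspring is assigned exactly as
real ones are, and the critical Δ is the smallest threshold such that the
stated fraction (default 80%) of assignments above it are correct; gaps of
+∞ (runner-up excluded outright) stay in the ranking. Separate thresholds
are calibrated for parent-pair and single-parent assignments. "Maximum of
three mismatches" is enforced as at most three mismatching loci per
comparison. Assignment tries the best valid pair first; failing the pair
threshold, the best single candidate is proposed as the mother (pollen
immigrant); failing that, the offspring is a seed immigrant. The spatially
nearer member of an accepted pair is labelled mother; palms are monoecious
so the pair itself is unordered.

Gene-flow rates are exact count ratios: s = selfed/total,
m_p = fatherless/total (parentless offspring included, as they also lack a
father), seed immigration = parentless/total. The parent-pair exclusion
probability uses exact moment formulas per locus (q_a = p_a(2−p_a),
r_ab = 2 p_a p_b) equivalent to full enumeration over genotype triples
under HWE, combined as 1 − Π(1−Q_l).

Dispersal summaries: pollen distance = distance between the two members of
an accepted outcross pair (selfed offspring excluded — a spike at zero
would distort the kernel comparison); seed distance = offspring to
assigned mother. The axial variance is σ_p² = Var(δ_p)/2 under isotropy;
Aep = 2πσ_p², radius = sqrt(Aep/π). Mating-frequency R² values are squared
Pearson correlations of per-class counts (ten equal-width classes spanning
the intermate-distance range) with class midpoints; the binning convention
is a package choice since several are in circulation. The KS test compares
pollen distances with the all-pairs intermate distances among candidates.

## Neighborhood mating model

Each offspring's likelihood mixes selfing (s), immigrant siring (m_p,
paternal gamete from the allele pool) and within-plot siring
(1−s−m_p) with father weights proportional to the exponential-power kernel
density at the mother-father distance, normalised over all candidate males
(the neighborhood is the whole plot). The kernel's normalisation constant
cancels in those weights, so only relative density at observed distances
is identified — the practical reason kernel parameters are weakly
identified from within-plot data (see Limitations). Mean dispersal
distance is δ = aΓ(3/b)/Γ(2/b); kernel sampling uses r = a·T^(1/b) with
T ~ Gamma(2/b), whose mean reproduces δ exactly.

Mothers are either fixed per offspring (e.g. the nearer assigned parent,
or simulation truth) or, by default when none are supplied, marginalised
over all candidates with seed-kernel weights on offspring-candidate
distances; in that mode the seed kernel's (a, b) join the fit, which is
how seed-dispersal kernels are estimated here. Optimisation is
derivative-free Nelder-Mead with jittered multi-start (default 8) on
transformed parameters — stick-breaking logits keep s + m_p ≤ 1, logs keep
a, b positive, and b is clipped to [0.1, 8] — because the (a, b) surface
is flat and often multimodal. Genotype transition products are
precomputed once as likelihood ratios against the unrelated hypothesis, so
each evaluation is a small weighted sum and the reported log-likelihood
adds the constant Σ ln P(g_o) back.

## Synthetic populations

The generator's defaults emulate the motivating field design: a 10 ha
square plot, 59 uniformly placed reproductive adults, 189 offspring in
three juvenile stages (70/60/59), 18 loci with 4–18 alleles drawn from
symmetric-Dirichlet(0.5) frequency vectors (floored at 1e-3 and
renormalised so every allele is drawable), selfing 0.04, pollen
immigration 0.40, an exponential pollen kernel with scale 250 m (δ =
500 m, matching the several-hundred-meter pollen transport typical of
insect-pollinated palms), an exponential seed kernel with scale 30 m (δ =
60 m, short-distance barochory/rodent dispersal that produces the observed
fine-scale SGS), genotyping error 0.01 and missingness 0.02. Offspring
positions are the mother's plus a seed-kernel displacement reflected at
the plot boundary, so the sample stays in-plot like a field census.
Immigrant fathers share the plot's allele frequencies by default — the
conservative choice that makes immigration hardest to detect — with a
Dirichlet-resampling divergence knob to create private alleles. The
error model replaces a genotype with a random HWE draw at rate e,
consistent with the likelihood's error term.

What the generator does **not** emulate: overlapping generations and
temporal structure, marker mutation, null alleles and allele-size binning
artefacts, clustered recruitment beyond the seed kernel, habitat
heterogeneity, and real immigrant allele-frequency divergence (unless the
knob is turned). Passing recovery tests therefore demonstrate estimator
correctness under the stated model, not robustness to every field
complication.

## Numerical and testing choices

Permutation p-values include the observed statistic ((b+1)/(B+1)), so they
are never zero. Default seeds are fixed (20140000) and recorded in every
output. Package defaults keep the field-standard Monte Carlo sizes (1,000
F permutations; 10,000 SGS permutations; 10,000 Δ replications); the test
suite and the pipeline's `fast` profile use smaller sizes (99–2,000),
chosen so the statistical checks they feed — nominal type-I rates,
parameter-recovery bands — are insensitive to the reduction. Calibration
tests use 200 null replicates for the two permutation tests, 20 study-scale
replicates for parentage recovery and 10 for the neighborhood model; all
seeded.

## Known limitations

- The kernel shape b and scale a trade off strongly when fitted from
  within-plot matings in a plot smaller than the dispersal scale;
  individual-replicate δ estimates scatter widely (the recovery test
  asserts a median). This mirrors the behaviour of spatially explicit
  mating models generally and is why published kernel fits from compact
  plots should be read with care.
- Cryptic gene flow biases m_p downward slightly (an immigrant can match a
  candidate by chance); with 18 informative loci the bias is small (the
  no-immigration test bounds it at 5%).
- The single-parent fallback cannot distinguish "mother found, father
  immigrant" from "father found, mother immigrant"; the found parent is
  reported as the mother, consistent with how seed distances are defined.
- Exact ties in LOD rankings are broken by candidate order; with
  continuous allele frequencies ties essentially never occur.
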