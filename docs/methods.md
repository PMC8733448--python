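# Methods

## Model and estimators

All statistics are functions of per-locus reference-allele frequencies of
up to four populations at J biallelic loci, treated as independent (in
genomic data this corresponds to loci on different chromosomes or at least
a megabase apart).  Population frequencies are estimated by a linear
estimator p̂ = Σₖ φₖ Xₖ, where Xₖ = dosageₖ/mₖ is the within-individual
frequency, mₖ ∈ {1, 2} the ploidy of individual k at the locus, and φₖ a
weight.  Two weighting schemes are implemented:

- **sample proportion**: φₖ = mₖ / Σ m — each sampled allele counts once;
- **BLUE**: φ = K⁻¹1 / (1ᵀK⁻¹1) with K the pairwise kinship matrix — the
  minimum-variance linear unbiased scheme; it reduces to the sample
  proportion when all individuals are unrelated, noninbred and of equal
  ploidy, and is undefined (singular K) when the sample contains duplicated
  genomes such as identical twins.

Relatedness enters through the kinship coefficient Φ_wx (probability that
one allele from w and one from x are identical by descent; for w = x the
two alleles are drawn with replacement, so Φ_xx = (1/m)[1 + (m − 1)f] with
f the inbreeding coefficient).  The sample-level summary is the weighted
mean pair kinship Φ₂(P) = Σ_w Σ_x φ_w φ_x Φ_wx, which is strictly positive
for any sample because the self terms never vanish.  The exact second
moment E[p̂²] = p² + Φ₂ p(1 − p) drives every bias below.

For the statistics that square a frequency from one population (G, F2, F3
and their normalized ratios), three estimator variants are provided.
Writing Ĝ(P_j) = p̂(1 − p̂):

- **hat** (plug-in): biased by +Φ₂(P_j) G(P_j) per squared-frequency
  population (downward for G);
- **tilde** (kinship-aware): subtracts Φ₂(P_j) G̃(P_j) with
  G̃(P_j) = Ĝ(P_j)/(1 − Φ₂(P_j)); exactly unbiased for G, F2, F3 under
  arbitrary relatedness and inbreeding;
- **breve** (finite-sample): subtracts Ĝ(P_j)/(Σm − 1); unbiased only for
  unrelated noninbred samples.  With sample-proportion weights and such a
  sample, Φ₂(P_j) = 1/Σm and tilde ≡ breve exactly.

F4 samples one allele per population per locus and is unbiased as a
plug-in; D and the four DFOIL ratios have unbiased numerators and
denominators and are approximately unbiased as ratios of locus means.
Normalized F3 (ratio over 2G(A)) and normalized F4 (ratio over G(P), no
factor 2) use variant-matched denominators.

Ratio statistics are ratios of means over loci, not means of ratios.
Standard errors use a delete-one-block jackknife over contiguous locus
blocks, recomputing the full ratio per deletion; the default block is one
locus, appropriate for unlinked loci, and configurable for dense data.

### Missing data and degenerate inputs

An individual missing at locus j is dropped from that locus only; weights,
Φ₂(P_j) and Σm are recomputed over the individuals present.  A locus where
every individual is missing is an error, as is a tilde correction at
Φ₂ = 1 (a single haploid carries no information about heterozygosity) and
a zero normalizer in any ratio statistic; degenerate loci are never
silently dropped.  Monomorphic loci are retained if present in the input.
Allele orientation follows the VCF REF allele throughout; F2/F3/F4 are
invariant to consistent relabeling, and D follows the sign convention of
its definition with REF as the counted allele.

## Pedigree kinship

Autosomal kinship uses the classical tabular recursion with founders
assumed unrelated and noninbred (founder inbreeding can be injected via a
kinship-table override): Φ_xy = ½(Φ_x,sire(y) + Φ_x,dam(y)) processing
individuals parents-first, Φ_xx = ½(1 + Φ_sire(x),dam(x)), f_x =
Φ_sire(x),dam(x).  X-linked kinship treats males as haploid (Φ_xx = 1)
carrying a maternal allele, while fathers transmit their single X to every
daughter; this yields brother–brother Φ = 1/2, sister–sister Φ = 3/8 and
brother–sister Φ = 1/4 for full siblings.  Kinship models are per locus
class: autosomal and X-linked loci get separate matrices.  The avuncular
coefficient (1/8) assumes the connecting siblings are outbred full
siblings.

## Theoretical bias, variance and MSE

Biases are evaluated from their closed forms: the Φ₂-weighted G sums for
hat variants, the (Φ₂Σm − 1)/(Σm − 1)-weighted sums for breve variants,
zero for tilde and for F4/D.  Ratio-statistic biases use the
ratio-of-means approximation, e.g. for the normalized F3 plug-in,
bias ≈ T/(G(A) − T) · (F3-normalized + ½) with T the mean of Φ₂(A_j)G(A_j),
and the X(P)/Y(P) components for the breve ratios; no delta-method
refinement is added.

Variances are obtained by expanding each per-locus estimator as a
polynomial in the (independent) per-population frequency estimates and
taking expectations with a cumulant closure for the moments of
ε = p̂ − p:

- E[ε²] = Φ₂ p(1 − p) (exact);
- E[ε³] = κ₃ and E[ε⁴] = 3(E[ε²])² + κ₄, where κ₃ = pq(q − p)/S² and
  κ₄ = pq(1 − 6pq)/S³ are the finite-sample skewness/kurtosis of a plain
  count of S sampled alleles.

Keeping the 3σ⁴ (Gaussian-sum) term matters: without it, squared-frequency
variances are underestimated by tens of percent wherever the frequency
contrast is small.  What the closure deliberately drops is the
relative-pair inflation of κ₃/κ₄ — a trio/quadruple identity-by-descent
quantity of the class (Φ₃, Φ₄, Φ₂,₂) treated as negligible throughout,
under the standing assumption that no individual is related to more than
one other in its sample and that populations are mutually unrelated.
Against exact enumeration and ≥10⁵-replicate Monte Carlo the engine agrees
to ≈0.03 % at a 120-individual (60 parent–offspring pair) configuration and
to within ≈2 % at a 20-individual one, where the dropped trio-IBD skewness
term is the dominant residual.  Ratio-statistic variances use the
delta method on the ratio of locus means (numerator variance, denominator
variance and their per-locus covariance).

MSE = variance + bias²; for tilde variants the MSE equals the variance.
Three scan modes reproduce the comparative analyses: a composition scan
over all mixtures of three relative types at fixed total pairs (1326 grid
points for 50 pairs), a sample-size scan with every individual in a
relative pair, and a true-value scan over replicate J-locus draws from a
frequency pool.  Scans evaluate theory only.  A structural note: the hat
bias of unnormalized F2/F3 does not depend on the true statistic, so the
MSE gap between hat and tilde varies with the true value only through the
bias of the ratio statistics (proportional to the true value for
normalized F4, which therefore shows the vanishing-at-zero, quadratic gap)
or through correlation between per-draw heterozygosity and differentiation
in the locus pool.

## Synthetic data

The generators define the package's study conditions.

**Relative pairs.**  A pair of a given type shares zero, one or two
alleles identically by descent per locus with probabilities (Δ0, Δ1, Δ2):
parent–offspring (0, 1, 0), full siblings (¼, ½, ¼), avuncular (½, ½, 0);
X-linked sibling variants carry their own ploidies, with sisters sharing
the paternal X always (Δ = (0, ½, ½)).  The copy construction replaces
y's genotype with x's with probability Δ2 and y's first allele with x's
first with probability Δ1, independently per locus; for diploid noninbred
pairs the implied kinship is Δ2/2 + Δ1/4.  Inbred full siblings (offspring
of a full-sib mating, Φ = 3/8, f = ¼) are instead produced by explicit
gene dropping through the four founder alleles, because the Δ construction
is only defined for noninbred pairs.

**Exact enumeration.**  For small samples the exact distribution of the
sample frequency is computed by convolving per-block count distributions
(binomial for unrelated individuals, full enumeration for each pair
construction), and expectations of arbitrary estimators are taken over the
product space across populations.  This oracle is exact to floating-point
rounding and validates the unbiasedness and bias results at 1e−12.

**Wright–Fisher divergence/admixture.**  The demographic experiment uses
per-locus binomial resampling of 2Ne allele copies in place of
sequence-level forward simulation: an initial frequency is drawn at the
split (default law: neutral-equilibrium SFS, density ∝ 1/x on the
1..2Ne−1 copy grid; Uniform(0.05, 0.95) as an alternative), the B- and
C-lineages drift independently for t_split − t_admix generations,
population A is founded as αb + (1 − α)c, and all three lineages drift for
the final t_admix generations.  Defaults follow the human-inspired
scenario: Ne = 10⁴ diploids, split 2000 generations before sampling,
admixture proportions 0.4/0.6 at 400 generations.  Loci fixed for the same
allele in all populations at sampling are flagged and excluded from
parametric statistics (polymorphism ascertainment).  Under pure drift the
expected parametric F3(A;B,C) of this model is

    E[h₀] · [ (1 − (α² + β²)(1 − μ)) (1 − λ) − 2αβ(1 − μ) ],

with λ, μ the per-branch heterozygosity decay factors (1 − 1/2Ne)^t of the
post-admixture and post-split epochs and E[h₀] the mean initial p(1 − p);
at the default parameters this is ≈ −0.018 · E[h₀], i.e. a small negative
value whose magnitude depends on the initial frequency law (≈ −0.002 under
the neutral SFS with ascertainment).  The acceptance script reports this
simulated quantity with a Monte-Carlo confidence interval rather than
assuming any particular rescaling convention.

**What the generators do not emulate.**  Loci are unlinked and mutation-
free within the simulated epochs (no new variants arise after the split;
real sequence data would add young population-private polymorphism, which
shifts the composition of ascertained loci).  There is no genotyping
error, no ascertainment toward common variants, and no selection.  Passing
tests therefore demonstrate correctness of the estimators and calculus
under the stated sampling model, not robustness to those complications.

**Seeding.**  All randomness flows from numpy Generators; replicate-heavy
experiments split a single seed via `SeedSequence.spawn`, so runs are
reproducible bit-for-bit at fixed seed.

## Problem sizes used in the packaged experiments

The test-suite experiments use J = 20 loci (matching the replicate design
the statistics are usually quoted for), 10³ replicates for bias-removal
checks, 10⁵ replicates for variance calibration, and 3×10⁴-locus
Wright–Fisher panels with 300 replicate samples for the admixture
experiment; the acceptance script averages 8 independent 2.5×10⁴-locus
panels.  These sizes give Monte-Carlo standard errors comfortably inside
the tolerances asserted.

## Known limitations

- Kinship is an input (pedigree or table); no genotype-based relatedness
  inference is attempted.
- Variance formulas are approximations: exact in Φ₂ products, missing
  trio-and-higher IBD contributions, hence slightly off (either direction,
  a few percent at small samples) when such terms are non-negligible; with
  many relatives of higher-order structure (e.g. sibling trios) they
  underestimate.
- Ratio-statistic biases use the ratio-of-means approximation and are
  flagged approximate; the tilde ratio estimators are approximately, not
  exactly, unbiased.
- Only biallelic loci, ploidies 1 and 2, and at most four populations per
  statistic are supported; no admixture-graph fitting.
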