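# Methods

This note documents the models implemented in erosionkit, the conventions
chosen where several were defensible, the defaults and what they mean, and
what the synthetic-data generator does and does not emulate.

## Genotype likelihoods and site filters (`erosionkit.gl`)

**Error model.** Reads aligned to a haploid sequence (in practice the
mitochondrial genome, which has a single allele per individual) give a
direct error estimate: `e` = mismatching bases / total bases among bases
with quality ≥ `min_quality` (default 30). A transversion-only variant
counts only transversion mismatches and multiplies by 3/2, since two of
the three possible miscalls from any base are transversions. `e` is
bounded above by 0.75 (beyond that the likelihood model degenerates).

**Likelihoods.** For genotype (a₁, a₂) the per-read probability is
`[P(b|a₁) + P(b|a₂)]/2` with `P(b|a) = 1−e` if `b = a`, else `e/3`; the
site likelihood is the product over reads, stored log-scaled and
normalized so the per-triplet maximum is 1 on the linear scale.
Individuals without reads carry flat triplets rather than being dropped,
so the minimum-individuals filter counts individuals with at least one
read. Major and minor alleles are the two highest-count bases across all
individuals, with ties broken in base order A<C<G<T — a fixed, documented
rule, since allele-count polarization alone does not determine ties.
Inside log-likelihoods `e` is floored at 1e-12 so that an error rate of
exactly zero remains well-defined.

**Allele frequencies and the SNP test.** Per-site minor allele frequency
is the EM fixed point of the standard Hardy–Weinberg mixture (posterior
genotype weights at the current `f`, then `f ←` mean expected minor dose
/ 2), iterated to `|Δf| < tol`. The SNP test is the likelihood-ratio
statistic `2[ℓ(f̂) − ℓ(0)]` against a 1-df chi-square, with the boundary
convention p = 1 when `f̂ = 0`; the ½χ²₀ + ½χ²₁ mixture refinement is not
applied, which is conservative. Filters run in a fixed order —
transversion filter after major/minor inference, then MAF, LRT and
minimum-individuals thresholds — and the minimum-individuals count is
taken after transversion removal.

## Heterozygosity and coverage calibration (`erosionkit.hetcal`)

**Two-class mixture.** Per individual, each site's genotype triplet is
folded to (homozygous, heterozygous): the homozygous class takes the
*maximum* of the two homozygote likelihoods rather than their sum — after
polarization one homozygote dominates, and the max avoids double counting;
this is a documented point of possible divergence from folded-SFS tools
that sum. Genome-wide heterozygosity is the heterozygous weight of the
two-class mixture fitted by EM: `p_k ← (1/S) Σ_s p_k L_sk / Σ_j p_j L_sj`
until `max|Δp| < 1e-8`. Initialization is (0.999, 0.001) because
heterozygous sites are rare; a flat initialization reaches the same fixed
point more slowly. If every site is uninformative the initialization is
returned with an explicit flag. Windows are 1 Mb, non-overlapping; windows
with under 10% informative sites are dropped; per-individual summaries are
site-weighted means across windows.

**Why calibration is needed.** At low depth a heterozygous site often
shows only one of its alleles, so raw estimates are biased downward, and
the bias grows as coverage falls. The calibration rebuilds the classic
downsampling design: one high-coverage individual is binomially thinned to
fractions (0.25, 0.40, 0.50, 0.60, 0.80) of its depth, three independent
replicates each — 15 datasets — heterozygosity is re-estimated from each,
and relative heterozygosity (ratio to the full-coverage estimate) is
regressed on achieved coverage with a degree-3 polynomial.

**Anchored fit.** The polynomial is fitted in the constrained form
`p(x) = 1 + (x − ref)·q(x)` (ordinary least squares on `y − 1`), which
forces the curve through (reference coverage, 1): the full-coverage
estimate *defines* "authentic" heterozygosity, so correction at the
reference coverage must be the identity. An unconstrained fit normalized
after the fact extrapolates badly beyond its highest support point (~80%
of the reference coverage) and distorts every prediction. Correction
divides the raw estimate by the predicted relative heterozygosity, clipped
below at 0.05, and refuses to extrapolate outside
[0.5 × min fitted coverage, 1.5 × reference coverage].

**Published coefficient presets.** Two published correction polynomials
are shipped verbatim as named presets (`PRINTED_CORRECTION_PRESETS`) but
are never applied by default: evaluated at their own reference coverage
they do not return 1, so their coverage normalization cannot be
reconstructed from the coefficients alone. The default is always a freshly
fitted curve.

**Observed bias magnitudes.** Because the two-class EM uses correct
per-site likelihoods, it is close to consistent even at 3×; across probe
simulations the uncorrected bias at ~3× is −12% to −18%, and correction
brings estimates within ±7% of truth. Pipelines built on hard genotype
calls, or estimators that must also learn their error model, show
substantially larger low-coverage biases; the calibration corrects
whatever multiplicative bias the chosen estimator has.

**Damage and transversions.** Post-mortem C→T/G→A damage is not part of
the likelihood model; at typical damage rates (~2%) it would dominate true
heterozygosity at historic-like coverages. Heterozygosity is therefore
measured on transversion sites only whenever damaged libraries are in
play (`exclude_transitions=True`, and the pipeline masks transition
major/minor pairs). This scales the measure by the transversion share of
polymorphism but leaves epoch contrasts intact.

**Group comparisons** use the rank-based Kruskal–Wallis H with tie
correction (via scipy); all-identical input returns (H = 0, p = 1) rather
than an error.

## Runs of homozygosity (`erosionkit.rohscan`)

The scan slides a 50-SNP window along each scaffold; a window is
homozygous if it contains at most 1 heterozygous and at most 5 missing
calls; each SNP's hit rate is the fraction of windows containing it that
are homozygous; SNPs with hit rate ≥ 0.05 seed segments; runs of
consecutive qualifying SNPs break at gaps over 1000 kb; emitted segments
must contain ≥ 50 SNPs, span ≥ 1000 kb and have density ≤ 50 kb/SNP.
Only the window size, minimum length and gap are commonly reported;
the remaining parameters are pinned to the scanning tool's documented
defaults and recorded in output headers. Coordinates are 1-based
inclusive and segment length is `end − start + 1` (the `.hom`
convention). The implementation is vectorized with cumulative sums and is
verified against an exhaustive plain-loop window enumeration in the tests.

FROH divides the cumulative length of segments exceeding 1 Mb by the total
length of scaffolds longer than 10 Mb. Length classes are
[0.5,1), [1,2), [2,5), [5,10), [10,∞) Mb, lower-inclusive — the class
labels in common use overlap at their boundaries, so a convention was
required. ROH calling expects a polymorphic SNP panel; scanning
monomorphic sites would trivially saturate, and panels sparser than
~1 SNP / 50 kb defeat the density filter, so desk-scale demonstrations use
SNP-dense simulations.

**Age dating.** Two conventions are implemented and never blended. The
formula as usually *stated* is `g = 100/(2rL)` (r in cM/Mb, L in Mb), but
the class-to-generation values quoted alongside it — 200 generations at
0.5 Mb, 100 at 1 Mb, 50 at 2 Mb, 20 at 5 Mb, 10 at 10 Mb — satisfy
`g = 100/(rL)`. The default convention `as_applied` reproduces those
quoted values; `stated` evaluates the formula as written (half the
generations). Years are `g ×` generation time (default 6, the accepted
koala value; r defaults to 1 cM/Mb).

## Mitochondrial haplotypes (`erosionkit.mthap`)

Alignment columns whose missing fraction (gap/N/?) exceeds the policy
threshold (default 0.10) are masked for all sequences; sequences still
containing missing characters are excluded and reported; identical
remaining sequences collapse to one haplotype.

Haplotype diversity is Nei's `Hd = n/(n−1)(1 − Σ pᵢ²)` with `pᵢ` the
relative frequency of haplotype *i* in the group.

**Permutation test.** The statistic is ΔHd between the two groups; the
exchangeable unit is the individual; pooled assignments (pooled by
*sequence*, so tables collapsed independently compare correctly) are
re-split into the original group sizes; the p-value is add-one,
`(1 + #extreme)/(1 + n_permutations)`, two-sided on |ΔHd| by default,
with 10,000 permutations. Under a simulated null the p-values are
uniform (KS distance < 0.05 at 1,000 replicates — tested). Note the test
has modest power for moderate diversity differences at n of a few dozen:
in the five-haplotype rare-loss scenario (historic frequencies
.4/.3/.15/.1/.05, contemporary missing the two rarest, n = 30/25) power
at α = 0.05 is only ≈ 0.26 two-sided (≈ 0.35 one-sided), so a
non-significant result in one draw of that scenario is unremarkable.

**Median-joining network.** ε = 0 only. Start from the minimum spanning
network over observed haplotypes (every edge that occurs in some minimum
spanning tree: endpoints not connected by strictly shorter edges);
repeatedly propose column-majority consensus vectors of connected node
triplets, keeping the proposal that most reduces the total minimum
spanning length, until none helps; prune inferred medians that end with
degree < 3. Three-way column ties keep the first sequence's state (rare
with four bases). Larger ε and full quasi-median refinement are out of
scope. Tests sandwich the result between the observed-only spanning length
and an exhaustive Steiner-point optimum on small instances.

## Population structure (`erosionkit.structure`)

The covariance between individuals i, j is
`C_ij = (1/L) Σ_s (E[g_is] − 2f_s)(E[g_js] − 2f_s) / (2 f_s (1 − f_s))`
with `E[g]` the posterior expected minor dose under a Hardy–Weinberg prior
at the estimated frequency; sites with `f` outside [0.05, 0.95] are
excluded (the same 0.05 threshold as the GL-stage MAF filter — no second
threshold is introduced). PCA is the spectral decomposition, eigenvalues
descending, scores scaled by √eigenvalue.

Admixture uses the standard GL admixture model: individual allele
frequency `h_is = Σ_k q_ik f_ks`, binomial(2, h) genotype prior, and EM
updates that attribute expected minor/major allele copies to clusters.
`F` is clipped to [1e-5, 1−1e-5] each update to avoid boundary
absorption. "Many runs, keep the best" is interpreted as independent
random starts (Q from a flat Dirichlet, F uniform), returning the highest
final log-likelihood with all per-start likelihoods retained; the
log-likelihood is non-decreasing within every start (EM guarantee,
tested). The production default is 100 starts; desk-scale analyses in the
tests and acceptance script use 3–5 starts on panels where all starts
agree to within label permutation.

## Synthetic data (`erosionkit.simdata`)

**What it emulates.** Two epochs separated by a diversity bottleneck;
per-individual coverages in the ~1–17× range of mixed museum/modern
datasets; sequencing error; strand-collapsed aDNA damage; autozygosity of
controlled tract length; epoch-specific mitochondrial haplotype
frequencies with loss of rare haplotypes.

**Genotypes.** Site frequencies are drawn from a neutral-like SFS with
density ∝ 1/x truncated to [1/2N, 1 − 1/2N] (2N = 100 by default, which
avoids zero-frequency sites). `theta` is the expected per-site
heterozygosity of the historic epoch: each site is polymorphic with
probability `theta / E_SFS[2p(1−p)]` and monomorphic otherwise, so
`theta = 0` gives an invariant genome and the expectation is exact. The
bottleneck is implemented as t generations of Wright–Fisher binomial
resampling at size 2N, with t chosen so `(1 − 1/2N)^t` equals
`bottleneck_factor`; expected contemporary heterozygosity is therefore
exactly `bottleneck_factor ×` historic, and a factor of 1 is the identity.
Sites are independent (no linkage) except planted tracts — every
downstream statistic here is per-site or tract-based. Genotypes are
Hardy–Weinberg draws per epoch; recorded "true heterozygosity" is the
realized fraction of heterozygous sites per individual.

**Planted ROH.** Tract lengths are drawn from a mix over the five length
classes (default uniform; the open top class is capped at 20 Mb for
drawing), placed uniformly without overlap, and every site inside a tract
is forced homozygous for an allele drawn from the site's epoch frequency.
The realized FROH lands within ±10% relative of the target or the call
errors out as infeasible.

**Reads.** Depth is Poisson(coverage) per site; each read carries one of
the two genotype alleles uniformly; damage converts template C→T and G→A
with probability `damage_rate` (strand-collapsed, position-independent —
downstream transversion filters act on transitions regardless of read
position, and a constant rate keeps expectations analytic; real aDNA
damage is concentrated at fragment ends); sequencing error then flips the
base to one of the three others uniformly with probability `error_rate`.
Qualities are the Phred equivalent of the error rate. Pileups store
per-(individual, site) base counts — read order never matters downstream,
and binomial thinning of counts is distributionally identical to per-read
retention for downsampling.

**Mitochondria.** Haplotype sequences grow on a random genealogy (each new
haplotype copies an existing one plus 1 + Poisson(2) substitutions at
fresh positions, guaranteeing pairwise distinctness); historic frequencies
default to a flat Dirichlet draw or are supplied; the contemporary epoch
drops the rarest haplotypes and renormalizes.

**What it does not emulate.** Linkage and recombination, selection,
end-weighted damage profiles, mapping and reference bias, index hopping or
contamination, and population substructure within an epoch (the
two-population Balding–Nichols panel is a separate generator for
structure analyses). Tests passing on these simulations therefore
demonstrate estimator correctness under the stated models, not robustness
to every artifact of real degraded-DNA data.

**Defaults** (the simulated study conditions): 20 + 20 individuals, 5 × 20
Mb scaffolds, 50,000 sites, theta = 0.0014 (the scale of reported koala
genome-wide heterozygosity), bottleneck_factor = 0.3 (matching the
observed historic:contemporary ratio), coverages 4× (historic mean) and
12.3× (the reference contemporary genome), error 1e-3 (Q30), damage 0.02,
mutation rate 1.905e-8 per site per generation and generation time 6
years.

## Problem sizes and numerical choices

Desk-scale analyses use 5e4–1e5 sites per individual, chosen so that
Monte-Carlo error in per-individual heterozygosity (hundreds to a
thousand heterozygous sites) sits well below the tolerances being tested.
EM tolerances: 1e-8 for the two-class heterozygosity mixture (and its
windowed use), 1e-8 for allele frequencies (1e-12 when compared against
grid oracles). Degenerate inputs are explicit: flat-likelihood sites are
uninformative, not errors; empty filter results warn rather than raise;
zero-coverage pileups are valid and empty. All generators and analyses
take integer seeds, and the pipeline manifest records every seed used, so
reruns are bit-identical.

## Known limitations

* The two-class heterozygosity estimator assumes the stated error rate is
  correct; it does not learn error or damage parameters site-by-site, so
  damaged libraries must be handled via transversion masking.
* ROH detection needs a dense SNP panel (≳ 1 SNP / 50 kb) and suffers at
  low coverage, where missing hard calls break windows; this mirrors the
  behavior of the underlying windowed algorithm, not a removable defect.
* The median-joining implementation targets the small haplotype sets
  typical of intraspecific mitochondrial data; its exhaustive triplet
  search is not intended for hundreds of haplotypes.
* The permutation test's power depends strongly on group sizes and the
  shape of the haplotype frequency spectrum (see above); it is exact in
  level but not powerful at small n.
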