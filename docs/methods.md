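# Methods

`demosfs` infers the joint demographic history of three diverging lineages
(labelled MOJ, SIN, SON after the Mojave, Sinaloan and Sonoran desert
tortoise populations that motivated the design) from the folded joint
allele-frequency spectrum (AFS) of synonymous transcriptome SNPs, two
diploids per lineage. This note records the model, the numerical choices
and the limits of what the test suite demonstrates.

## Model and likelihood

All demographies are parameterised relative to the ancestral effective size
Na: sizes `nu = N / Na`, epoch durations `T` in units of 2·Na generations,
migration rates `m = 2·Na·m_raw` (fraction of the recipient population
replaced per generation, times 2·Na), and the mutation scale
`theta = 4·Na·mu·L`. The three-population topology is fixed at
((SIN, SON), MOJ): Mojave diverges `T1 + T2` ago, the Sinaloan and Sonoran
lineages `T2` ago; the internal Sinaloan+Sonoran branch carries
`nu_sinson`, which the contemporary Sinaloan population inherits; the
ancestral size is the unit. The registry also carries two-population
isolation, isolation-with-migration (IM) and secondary-contact variants
used for pairwise analyses and gene-flow hypothesis tests.

The data likelihood is a Poisson composite likelihood: each unmasked cell
of the folded spectrum contributes a Poisson term with mean
`theta * m_c`, where `m_c` is the expected per-unit-theta spectrum entry.
Sites are treated as independent even though sites within a contig share a
genealogy; the dependence is handled downstream (bootstrap, Godambe
correction), not in the likelihood. Because the expectation is linear in
theta, `theta_hat = sum(data)/sum(model)` maximises the likelihood exactly
and is profiled out of every optimisation.

## Expected spectra (the engine)

Expected spectra are computed exactly from the structured coalescent; no
diffusion approximation or simulation enters the fitted quantity. Entry
`c` equals half the expected total branch length (in 2·Na-generation
units) subtending exactly the sample configuration `c`.

For migration-free epochs the computation exploits a classical property of
the coalescent: the embedded jump chain (which pair of lineages merges
next) is uniform over pairs, independent of population size and holding
times. The chain over *configurations* — multisets of ancestral blocks,
each block labelled by how many sampled chromosomes it subtends per
population — is therefore parameter-free and is tabulated once per
sample-size signature (for 4+4+4 chromosomes: 6,721 configurations).
Parameters enter only through the occupancy times of the pure-death chain
on the number of surviving lineages, computed from a ≤24×24 matrix
exponential per branch. One trio spectrum evaluates in about a
millisecond, which is what makes multi-start fitting and one hundred
bootstrap re-fits affordable on one CPU.

Epochs with active migration lose this factorisation because lineage
locations matter: there the full continuous-time Markov chain over located
configurations is used (1,431 states for 4+4 chromosomes). Its generator
decomposes into four parameter-free sparse components (coalescence per
deme, migration per direction), so each evaluation reduces to one sparse
matrix-exponential action (~10 ms).

Numerical character: evaluations are deterministic, smooth in the
parameters (matrix exponentials are analytic; the test suite verifies that
1e-6 perturbations move no cell by more than 1e-3 relative), and exact up
to floating point. An internal sanity check raises if entries come back
negative beyond 1e-8 or non-finite. Folding ties (cells whose total
allele count is exactly half the sample) are counted once, in the
lexicographically smaller member of the complementary pair.

Validation is two-route: closed forms (the equilibrium `theta/i` spectrum;
a zero-time split equals the panmictic spectrum redistributed
hypergeometrically; a high-migration island model converges at rate 1/m to
panmixia) and an independent Monte-Carlo oracle that averages msprime
branch-mode AFS over replicate genealogies under the identical demography.
The oracle comparison is z-score based with two statistical cautions: the
per-cell z-scores are positively correlated (cells share replicates), so
the suite bounds the mean squared z and the worst cell rather than
imposing a per-cell band whose expected maximum a perfect engine would
exceed; and per-cell comparison is restricted to cells whose relative
Monte-Carlo error is below 10% at 3e4 replicates, with the remaining
sliver (cells hit by only a handful of genealogies, whose empirical SE
is itself unreliable) compared in aggregate — the machinery behind rare
cells is additionally verified at sample sizes where no cell is rare.

## Optimisation

Fits are multi-start (default 20): the starting vector is perturbed
log-uniformly within a factor of two per coordinate, clipped to bounds
(sizes 1e-3–1e3, times 0–10, migration 0–20), and each start runs a
bounded Nelder-Mead simplex (sizes on a log scale, times and migration
linear) polished by L-BFGS-B. Convergence tolerance is 1e-6 in
log-likelihood; ties between starts are broken by distance of the end
point from the median start, keeping results reproducible for a given
seed. Bootstrap re-fits warm-start from the full-data optimum with three
perturbed restarts. Every reported fit satisfies the self-consistency
invariant that its log-likelihood equals the likelihood recomputed at its
parameters.

## Uncertainty under linkage

Confidence intervals come from conventional bootstraps over contigs:
whole contigs are resampled with replacement (same number as observed),
the folded spectrum rebuilt, parameters re-fit, and intervals reported as
`mean ± 1.96·sd` across replicates (default B = 100).

Nested models are compared with a Godambe-information-corrected
likelihood-ratio test: with `H` minus the Hessian of the profiled
composite log-likelihood in the constrained directions at the nested
optimum (embedded in the full parameterisation) and `J` the mean outer
product of bootstrap score vectors at the same point, the raw statistic
`D = 2·(ll_full − ll_nested)` is rescaled by `df / trace(J·H^{-1})` and
referred to chi-squared on `df` degrees of freedom. With truly unlinked
sites `J ≈ H` and the adjustment is ~1 (verified); with linked contigs it
falls below 1 and restores type-I error toward nominal (verified by a
200-replicate null calibration in which the raw test's rejection rate
inflates and the adjusted test's is closer to 5%). Derivatives are
central finite differences with relative step 1e-2 and one-sided stencils
at bounds, which matters for migration rates tested against zero. No
boundary-mixture null is applied by default (plain chi-squared df), with
the 50:50 mixture available behind a flag for bound-constrained
parameters.

## Physical units

Scaled estimates leave Na undetermined; it is anchored by equating the
scaled Mojave divergence `T1 + T2` to 5.9 Ma under a 25-year generation
time: `Na = 5.9e6 / (2·25·(T1+T2))`, then `mu·L = theta/(4·Na)`, sizes
`nu·Na`, times `T·2·Na·g`. The converted Mojave divergence of the
full-data fit equals the anchor exactly, by construction. Bootstrap
replicates are converted with the full-data `mu·L` held fixed and each
replicate's Na taken from its own theta, so replicate divergence times
scatter around the anchor and the interval on the anchored time is
meaningful.

## Synthetic data

The generator emulates the statistical structure the analysis assumes: one
coalescent genealogy per contig (fully linked sites within a contig,
independent contigs; within-contig recombination available but off by
default, matching the exchangeable-contig assumption of the bootstrap),
7,665 contigs carrying on average 20,126/7,665 ≈ 2.63 *retained*
synonymous SNPs each, genotyped in two diploids per lineage under the
six-parameter best-fit demography (Na = 336,200; Mojave, Sinaloan and
Sonoran sizes 128,400, 149,600 and 600,000; divergences 5.9 and 5.65 Ma at
g = 25). Nuisance structure exercises the filters: 20% of sites labelled
nonsynonymous and 5% ambiguous, 5% given sub-threshold (<20) Phred
quality, and a 2% per-genotype missing rate; the mutation intensity is
inflated so the post-filter synonymous density hits the target. A
linkage-free fast path draws independent Poisson counts per spectrum cell
with the same expectations.

What passing tests therefore show — and do not show — about real data:
the pipeline recovers the generating demography from data whose sites are
genuinely linked within contigs and whose filters genuinely remove sites,
at the study's sample sizes and SNP counts. The generator does not
emulate genotyping error, allele-specific expression, selection at linked
sites, reference bias or annotation error, so the tests say nothing about
robustness to those; the real analysis mitigates them upstream by
restricting to unambiguous synonymous variants with complete genotypes.

## Problem sizes used by the test suite

The acceptance-scale experiment runs at the study's full size (~20k
retained SNPs, 7,665 contigs, 20 optimisation starts, 100 bootstrap
re-fits; a few minutes on one CPU thanks to the millisecond engine).
Property suites run scaled down by design: the null-calibration study
uses 200 replicates of 150 contigs × 5 SNPs with B = 30 bootstraps, and
oracle cross-checks use 1e4 coalescent replicates per parameter point.

## Known limitations

* Sample sizes beyond a few chromosomes per population grow the
  configuration spaces combinatorially; the exact engine is designed for
  the few-individuals/many-loci regime (it is comfortable at 4–6
  chromosomes per population, and the migration CTMC grows fastest).
* The composite likelihood is not a true likelihood; absolute
  log-likelihood values are meaningful only for comparisons on the same
  spectrum, and all test calibration under linkage flows through the
  bootstrap/Godambe machinery.
* Secondary-contact models clip the contact time at the split time
  (`Tc_eff = min(Tc, T)`), so the IM model sits on the boundary of the
  secondary-contact family rather than outside it.
* The trio topology is fixed; alternative branching orders are probed via
  pairwise divergence comparisons, not an exhaustive topology search.
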