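# Methods

## Models

The phenotype model is the standard animal model for a lactating cow
*i* in herd *j*, parity *k*, at *dim* days in milk:

    y = mu + herd_j + parity_k + b1*dim + b2*exp(-0.065*dim)
        + a_i (+ m_i) + e

with `a ~ N(0, A sigma2_a)` the additive-genetic effect, `m ~ N(0, M
sigma2_m)` the rumen-microbial effect, and independent residuals.  The
Wilmink term `exp(-k*dim)` with decay `k = 0.065 /day` absorbs the sharp
early-lactation nonlinearity; herd (6 levels by default) and parity (4
levels) are dummy-coded with the first level as reference.  Taxon-level
models (per-taxon heritability, ordination-axis heritability) replace or
augment the herd effect with sequencing batch nested within platform
(11 batches over 2 platforms by default), since library preparation is a
dominant technical source of abundance variation.

**A** is the pedigree numerator relationship matrix computed by the tabular
method, including inbreeding; unknown parents contribute zero and
undeclared parents are treated as founders.  Restricting A to phenotyped
animals after the full recursion is exact (the recursion for any pair
involves only their ancestors), which is why the pipeline prunes to
ancestors-of-phenotyped without changing any estimate.

**M** is the microbial relationship matrix `M = X X' / n` over the union of
retained bacterial and archaeal OTUs.  X is built in a fixed order: drop
samples under 50,000 reads (strict inequality); drop OTUs with total count
under 10, present in fewer than 50% of samples (exactly 50% is retained),
or with zero count variance; convert to per-sample relative abundance;
natural-log transform with a pseudo-abundance (default: half the smallest
nonzero relative abundance in the matrix, configurable and recorded in the
provenance trail — zeros must map to a finite floor and the data do not
dictate a unique choice); then center and scale each taxon to unit sample
variance (n−1 denominator) *within* each sequencing platform before
recombining.  Any overall scalar in X is absorbed into sigma2_m, so the
ratio m² is invariant to these normalization conventions; the within-
platform standardization is what removes instrument-level location/scale
artifacts from the kernel.  Kernels are not rescaled to unit mean diagonal:
ratios are scale-invariant either way and the definition of M is kept
literal.

## REML estimation

A single-kernel model is fit by profiling the REML log-likelihood over the
ratio `delta = sigma2_e / sigma2_k` after one eigendecomposition of the
kernel: a 57-point grid on `log delta` in [log 1e-6, log 1e8] brackets the
optimum and bounded scalar minimization refines it to `xatol = 1e-10`.
This is exact, fast (O(n) per likelihood evaluation after rotation), and
well behaved when the estimate sits on the zero boundary.

Multi-kernel models use average-information (AI) REML.  Each iteration
computes the projection matrix P, the score vector and the AI matrix; the
first step and any rejected step use the monotone EM-REML update instead.
AI proposals are projected onto the lower bound `1e-6 * sigma2_p(initial)`
per component; components pinned at the bound with negative score are
frozen out of the AI solve (active-set), which prevents the boundary
component from corrupting the Newton direction; the step is halved up to 8
times if the log-likelihood would decrease, so accepted iterations are
monotone.  Convergence is `|delta loglik| < 1e-8`, at most 200 iterations;
non-convergence flags the result rather than raising.  Both routes use the
same likelihood convention `-0.5 (log|V| + log|X'V^-1 X| + y'Py)` and agree
to machine precision on single-kernel problems (cross-checked in the test
suite against an independent brute-force grid evaluation).

Standard errors come from the inverse AI matrix at the optimum; ratio SEs
(h², m²) use the delta method with the full component covariance.  Ratio
confidence intervals are Wald (estimate ± z·SE): they reproduce the
arithmetic of published genus-level tables and are reported untruncated,
so a lower limit can be slightly negative near the boundary.  p-values for
ratios are two-sided normal.  Variance-component comparisons use the
boundary likelihood-ratio test with the 50:50 mixture of chi-square(0) and
chi-square(1), the correct null for one component tested at zero.

The per-taxon association scan defaults to P3D-style reuse: variance
components are estimated once under the covariate-free model and reused
for every taxon's GLS fit.  This is hundreds of times faster than exact
per-taxon re-estimation and agrees with it to within a few percent on the
effect sizes under moderate polygenic signal (checked in the tests); exact
mode remains available.  Only the pedigree kernel is included in the
association model — the scan asks what each taxon adds over familial
structure, and conditioning on M would absorb the very signal being
tested.

## Synthetic herds

The generator exists so every estimator has a ground-truth test bed with
the same covariance structure the models assume.

* **Pedigree.** Discrete generations; each generation mates `n_founders/2`
  dams to a pool of `n_sires` sires (default 25), each mating producing
  `offspring_per_mating` offspring.  The small sire pool creates the large
  paternal half-sib families typical of dairy cattle and is what makes h²
  estimable from a single phenotyped generation of ~1000 cows.  Breeding
  values are generated by gene dropping: founders N(0, sigma2_a),
  descendants the parental mean plus a Mendelian deviation with variance
  `0.5 sigma2_a (1 - (F_s + F_d)/2)`, so Cov(a) = A sigma2_a holds exactly
  even under inbreeding.
* **OTU counts.** Each taxon has a base log-abundance drawn N(0, 2²) —
  giving the strongly skewed compositions typical of 16S surveys — plus a
  unit-variance latent deviation.  For a `frac_heritable_otus` minority
  (default 10%, matching the observed few-percent share of heritable taxa)
  the latent deviation is an *independent* pedigree-correlated gene drop
  with variance fraction `otu_h2` (default 0.25, the magnitude of published
  genus-level estimates).  Per-(batch, taxon) shifts N(0, 0.3²) add
  technical structure.  Latent abundances are softmax-normalized per sample
  and realized as multinomial counts at a lognormal library size (mean
  100,000 reads, log-SD 0.25); a configurable fraction of samples is drawn
  uniformly between 10,000 and 49,999 reads to exercise the depth filter.
* **Phenotype.** `y = mu + fixed effects + a + m + e` with mu = 395.8 g/d
  and total variance (63.5 g/d)² = 4032 (g/d)².  The microbial effect uses
  per-taxon coefficients, `m = X b`, `b ~ N(0, sigma2_m / n_taxa)`, rather
  than a Cholesky draw from M: this makes Cov(m) = M sigma2_m exact *for
  the same X the estimator builds*, so parameter recovery is a valid
  acceptance surface rather than an approximation.  Genetic and microbial
  effects are independent, matching the joint model's assumption.  Herd
  effects are N(0, 25²) g/d, parity effects N(0, 15²) g/d, and the dim
  regressions are b1 = 0.10 g/d per day and b2 = −25 g/d — plausible
  magnitudes for lactation curves; their exact values are irrelevant to
  variance-ratio recovery because they are absorbed by the fixed effects.
* **Sampling frame.** When an OTU table is simulated, phenotypes are
  generated only for animals whose sample passes the depth filter: the
  microbial effect is undefined without usable microbiome data.  Recovery
  studies set the low-depth fraction to zero so n is exactly the configured
  herd size.

All randomness flows from one master seed through named substreams
(CRC32-keyed `SeedSequence` children), so outputs are bit-identical across
runs and independent across stages.

What the generator does **not** emulate: real 16S read error, chimeras or
clustering artifacts; phylogenetic correlation among taxa (taxa are
exchangeable given their base abundance); diet, season or herd-microbiome
interactions; genetic correlation between the heritable-taxon effects and
the phenotype's breeding values (the generative model makes them
independent, like the estimating model).  Passing recovery tests therefore
demonstrates correctness of the estimators under the assumed model, not
robustness to model misspecification in field data.

## Community structure

Bray–Curtis dissimilarity is computed on relative abundances (depths
differ between samples; on closed compositions the choice is
inconsequential).  PCoA Gower-centers `-D²/2` and eigendecomposes;
negative eigenvalues (Bray–Curtis is non-Euclidean) are reported as-is
with no Cailliez/Lingoes correction, and proportions explained use the
positive part of the spectrum.  Axis signs are fixed by making the
largest-magnitude coordinate positive, so output is deterministic across
linear-algebra backends.  Emitter deciles take the top and bottom
`floor(n/10)` animals with ties broken by stable id order; group contrasts
on ordination axes use the two-sided Mann–Whitney test, exact when both
groups have at most 8 members.  Ordination-axis variance is decomposed by
sequential (type I) ANOVA in the fixed, logged order herd, parity, batch,
dim, Wilmink; the order matters for non-orthogonal designs and is reported
with the shares.  Axis heritability uses the batch-adjusted animal model.
No discrete "ruminotype" clustering is performed: the gradient structure
of rumen communities does not support a unique cluster definition, and
none is assumed.

## Problem sizes for validation

The packaged recovery studies (tests and `scripts/acceptance.py`) use 40
replicate herds of 1000 phenotyped cows per scenario — three generations
from 1000 founders, 25 sires per generation — with 2000 taxa for the
microbial-only scenario and the default ~1100 for the joint scenario.
These sizes give replicate-mean standard errors near 0.01 on the variance
ratios, small enough to detect estimator bias at the 0.03 level while
keeping a full validation run in the minutes range on one core.  Smaller
herds (a few hundred cows) are used in unit tests where only correctness,
not precision, is at stake.

## Known limitations

* Wald intervals on ratios are symmetric and can cross 0 or 1 near
  boundaries; profile-likelihood intervals are not implemented.
* The P3D association mode slightly misstates per-taxon SEs when a taxon
  explains a non-trivial variance share; use exact mode for follow-up of
  top hits.
* The taxonomy collapser assumes greengenes-style `k__; p__; ...` rank
  prefixes (falling back to positional parsing) and groups rank-unassigned
  taxa under their nearest classified parent.
* A-inverse shortcuts (Henderson's rules) are deliberately absent: at the
  package's design scale (up to a few thousand animals) the dense tabular
  construction is simpler and fast enough.
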