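# Methods

This note documents the models behind `forensnp`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical decisions that matter when reproducing results.

## The problem setting

Degraded skeletal samples yield DNA that is fragmented, chemically
damaged and heavily diluted by environmental (non-endogenous) DNA.  Three
assay families are in scope downstream of read processing: a targeted
forensic SNP assay of a few thousand markers, a large hybridization-
capture panel of ~1.35 M SNPs, and shotgun whole-genome sequencing whose
mean on-target depth can be ~0.3×.  At such depths classical
threshold genotyping types almost nothing, while a genotype-likelihood
treatment of the raw allele depths still supports one-to-one identity
comparisons.  The package implements both routes plus the evaluation
metrics used to compare assays.

## Threshold genotype calling

Filters run in a fixed order — depth, quality, other-allele fraction,
strand balance, allelic balance — so every no-call carries exactly one
reason.  Decisions and defaults:

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 10 reads | minimum ref+alt depth |
| `min_quality` | Q20 | minimum mean Phred |
| `max_other_fraction` | 0.10 | max fraction of non-ref/alt reads |
| `strand_min_fraction` | 0.10 | minority-strand floor |
| `strand_check_min_depth` | 20 | depth below which the strand rule is skipped |
| `het_ab_low..high` | 0.30–0.70 | heterozygote allelic-balance band |
| `hom_ab_max` | 0.10 | max minor-allele fraction for a homozygote |

These are common forensic MPS practice; assays with internally validated
values can substitute them via the `force_like`/`twist_like` profiles or
the `calling:` config section.  The gap between `hom_ab_max` and
`het_ab_low` deliberately produces a no-call rather than a forced
genotype: an intermediate balance is precisely where drop-in/drop-out
artifacts live.  Depth for the balance decision counts ref+alt reads
only, so a third allele cannot silently shift the balance — it is
filtered by its own rule.  Replicate-consensus calling retains a marker
only when both replicates type it identically; discordant markers get the
dedicated no-call reason `replicate_discordant`.

## Direct-match likelihood ratio

Genotype likelihoods use the coefficient-free binomial kernel
`q^a (1-q)^(n-a)` over the ref/alt reads of a site; the binomial
coefficient cancels inside every per-SNP LR, so it is omitted (individual
likelihood values are therefore comparable only within a site).  The
effective per-read error is `ε_eff = min(k·ε, 0.49)` with base error
`ε = 0.01` and a sample-specific inflation factor `k = 2` by default; the
multiplicative interpretation of the sample factor is this package's
design choice for absorbing extra per-sample noise.  Allele frequencies
are clamped to `[0.001, 0.999]` so monomorphic markers cannot contribute
infinite penalties.

SNPs are treated as unlinked and their log contributions summed.  A
linkage-aware chain model would tighten LRs for dense panels but matters
far less for the identity hypothesis pair than for kinship; it is out of
scope.  The per-SNP ratio is evaluated entirely in log space
(log-sum-exp over the three genotypes): opposite homozygotes at depths in
the hundreds underflow linear arithmetic, and summing per-SNP logs (never
product-then-log) keeps 50,000-marker totals exact.

SNP selection for matching mirrors practice with low-input captures: the
autosomal markers with the highest total read count across all samples,
ties broken lexicographically by marker id, up to the requested count
(50,000 by default).

Classification defaults: a comparison is *inconclusive* below 150
doubly-covered SNPs, otherwise the sign of ln(LR) decides.  The floor
exists because false-positive comparisons concentrate where very few SNPs
are shared — capture bias can push a handful of markers the wrong way,
but not hundreds.

## Concordance and accuracy

"Typed" means call ≠ no-call; only markers typed in both call sets enter
a comparison.  Discordances partition exactly into *false homozygotes*
(het vs hom) and *contradictory homozygotes* (opposite homs).  Haploid
calls compare to diploid ones through their allele (hap_ref ≡ hom_ref,
hap_alt ≡ hom_alt; hap vs het counts as a false homozygote) — relevant
only when sex metadata is inconsistent between runs.  Accuracy against a
latent truth set maps calls to ploidy-aware dosages instead (hap_alt →
dosage 1).  Reported rates are rounded half-up to one decimal; raw
fractions are always retained.  Pooled discordance sums counts before
dividing — in general different from a mean of rates.  Y markers can be
excluded from concordance on request, since male-line relatives (and any
two males at low marker counts) share them disproportionately.

## Call rates and statistics

Call-rate denominators are sex-adjusted: females cannot be typed at Y
markers.  Unknown sex keeps the full panel as denominator (conservative)
and logs a warning.  The dynamic top-N call rate calls each sample's N
best-covered markers with the diploid rules and keeps N as denominator
even when fewer markers have coverage, so shallow samples are not
flattered.

The regression stage is ordinary least squares with an intercept and
two-sided t-tests per coefficient; rank-deficient designs are rejected
with advice rather than pseudo-inverted.  Assay comparison is a one-way
fixed-effects ANOVA on raw call-rate proportions (a logit/arcsine
transform can be applied by the caller if desired) followed by Tukey HSD
in its Tukey–Kramer form, valid for unequal group sizes.  The
planted-effect validation asks that the planted predictor be significant
at α = 0.01 *and* all five noise predictors non-significant; under exact
level-α tests the per-replicate success probability of that conjunction
is about `0.99^5 ≈ 95%`, so the check is run on pinned seed streams.

## The simulator

The generator emulates the statistical structure of degraded-sample read
counts, not the reads themselves.  Per-marker depth is negative-binomial
with mean `λ·t_j`, where `t_j` is a lognormal (median-1) capture
efficiency shared by all samples on a panel — capture efficiency is a
property of the marker/probe, which is also what makes "highest total
read count" selection meaningful.  The dispersion default (1.0) reflects
strongly over-dispersed empirical capture coverage; it is exposed in
config because no authoritative value exists for the panels of interest.

Each read is a contaminant with probability `c` (drawn from one
independent HWE individual per sample — simpler than a mixture and
sufficient for robustness testing), otherwise reflects the true genotype
through the same `q(g, ε)` kernel the LR uses; C/T- and G/A-typed markers
get an extra symmetric flip `δ` as a deliberately coarse stand-in for
terminal deamination.  "Other"-base reads occur at `ε/3` per read, strand
is a fair coin, and mean site quality is truncated-normal (≥ 2).
Run-level bookkeeping (total, human, duplicate, on-target reads) is
derived from the configured non-human and duplicate fractions; the
simulator does not model off-target human reads separately.

Presets: `wgs_like` (λ = 0.3, 90% non-human, 30% duplicates),
`capture_like` (λ = 30, lognormal σ = 0.8 site efficiency, 50% non-human),
`control_like` (λ = 100, clean).  What the simulator does **not**
emulate: position-dependent damage profiles, mapping quality, indels,
multi-allelic sites, linkage between markers, and library-chemistry
differences.  Tests passing on simulated data therefore validate the
*analysis* contracts (calling rules, LR arithmetic, metric definitions),
not the upstream read processing.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds carried in
configs; identical config + seed reproduces every table byte for byte.
The validation suite and the acceptance script use deliberately modest
problem sizes — 10,000-marker panels and 22-sample cohorts for the
ln(LR) separation study, 3,000–5,000 markers for caller and consensus
checks, 100 replicates for the planted-effect studies — chosen as the
smallest sizes at which the checked properties are statistically
unambiguous.

## Known limitations

* The LR ignores linkage; with ~50,000 markers from a dense panel the
  totals are modestly anti-conservative for closely spaced SNPs.
* The sample-error factor is a multiplicative stand-in; software packages
  implementing genotype-likelihood matching may parameterise
  sample-specific error differently.
* Contamination is not modelled in the likelihoods (only in the
  simulator), so heavily contaminated pairs can depress same-donor LRs.
* X-chromosome handling is limited to ploidy-correct calling; the LR uses
  autosomes only.
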