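# Methods

This note documents the models, defaults and numerical choices behind
`exprot`, and what the synthetic benchmark does and does not establish
about real data.

## Study design and data model

The unit of analysis is a paired crossover study: *n* subjects
(default 12) each complete one moderate- and one high-intensity exercise
bout, with plasma sampled immediately before and after each bout
(4 samples/subject, 48 total at the defaults). A fixed aptamer panel
(default 1,305 analytes) reports relative abundance on a positive,
RFU-like scale. Analytes are aptamer-indexed: proteins measured by
multiple reagents are carried as distinct analytes through testing and
deduplicated by gene symbol only where a stage operates on genes
(enrichment, tissue inference).

The generator writes log2 abundance as

    baseline_g + subject_offset_{g,s} + Δ_{g,i}·[post] + ε

with protein baselines N(10, 1.5²), per-(protein, subject) offsets
N(0, 0.25²) shared by all four of a subject's samples, planted effects
Δ on the post samples only, and iid measurement noise N(0, 0.08²).
A within-sample SD of 0.08 log2 units is a ~5.7% CV, in the range
reported for aptamer technical replicates; the subject offset models
stable between-subject level differences, which paired differencing
removes exactly. Responsive fractions default to 14% (moderate) and 46%
(high) of the panel with 159/184 of moderate responders shared —
the responsive-set sizes are rounded once and drawn disjointly
(shared / moderate-only / high-only) so partition counts are exact.
Planted |Δ| is 0.5·U(0.75, 1.25) log2 units, i.e. ≈6× the paired-noise
scale, and 65% of responders increase. Shared responders are strictly
concordant across intensities and carry a planted dependence class via
the linear fold-change ratio FC_H/FC_M ∈ {1.4, 1.0, 1.12}
(dependent / independent / intermediate, straddling the 1.25 and 1.05
classification boundaries), with proportions 22:44:93.

A single seed drives independent deterministic streams per generator
(cohort, tissue expression, gene sets, genetics), so each table can be
regenerated alone and the genetics generator can reproduce the response
plan without building the abundance matrix.

## Moderated paired testing

Per intensity, protein g is tested on subject-paired differences
d_{g,s} = log2(post/pre). The empirical-Bayes model places a scaled
inverse-χ²(d₀, s₀²) prior on the true variances, so the sample variance
satisfies s²_g/s₀² ~ F(d_g, d₀) with d_g = n−1. Hyperparameters are
fitted by the method of moments on z_g = log s²_g using the closed-form
digamma/trigamma expressions for E[log F] and Var[log F]; the trigamma
inverse is solved by Newton iteration (tolerance 1e-10). When the
observed dispersion of z does not exceed the χ² sampling contribution
trigamma(d_g/2), d₀ = ∞ and every protein uses the common variance.
Note the d₀ = ∞ inversion still removes the χ² log-bias, so s₀² is
exp(mean z) corrected by −(ψ(d_g/2) − log(d_g/2)); with all sample
variances equal this differs from the raw common value by design (the
unbiased inversion), and matches limma's `fitFDist`, against which the
whole path is cross-checked in the test suite.

The posterior variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) yields
t̃_g = mean(d_g)/(s̃_g/√n), referred to a t distribution with d₀ + d_g
degrees of freedom capped at the pooled residual df over all proteins
(information cannot exceed the pooled total; this keeps the d₀ = ∞
limit finite and matches limma's `df.total`). d₀ = 0 recovers the
ordinary paired t-test (`moderation: none`). Zero posterior variance is
an error, never p = 0. Two-sided p-values are adjusted by the BH
step-up q_(i) = min_{j≥i} p_(j)·m/j within each intensity over all
tests; per-intensity adjustment matches how per-intensity significant
sets and volcano plots are reported. Fold change is the geometric-mean
ratio 2^mean(d_g), robust to subject level offsets.

On null simulations the moderated p-values are uniform to within
binomial error (checked over 5 × 2,000 proteins) because, with a
correctly estimated prior, t̃ is exactly t-distributed under the
hierarchical model.

## Intensity dependence

The 25%/5% rules are applied on the linear fold-change scale with the
moderate response as baseline. For decreasing proteins the magnitude
ratio uses reciprocal fold changes (FC_M/FC_H) so r > 1 always means
"changes more at high intensity" — the published rule is stated only
for increasing proteins, and this is the monotone extension. Both
thresholds are boundary-inclusive; if the dependence and independence
rules could ever both fire, dependence wins (impossible for positive
FC_M at these thresholds). Classification is scale-invariant for
increasing proteins.

Observed discordance among shared responders is expected to be near —
but not exactly — zero: planted responses are concordant, so discordant
hits are FDR-permitted false positives at one intensity (typically a
handful per run at q < 0.05).

## Enrichment

The background universe is the platform's gene complement, not the
genome: a query can only be drawn from measured proteins, and a genome
background would inflate enrichment. The raw p-value is the binomial
upper tail P(X ≥ k) with X ~ Binomial(n, K/N) (a hypergeometric option
exists behind a flag; binomial is the primary test to match the
overrepresentation-test convention used with PANTHER-style tools).
Bonferroni m counts only sets with nonzero background overlap —
untestable sets are not comparisons. Results are ordered by fold
enrichment with raw-p and name tie-breaks for determinism.

## Tissue inference

p(tissue a) = TPM_a/ΣTPM is a normalized share, so the proportionality
constant in the defining relation is fixed at 1 — any other value would
break Σp = 1. Proteins mapping to several genes use the mean of the
genes' probability vectors; proteins with no mapped gene or all-zero
expression are dropped and counted in the profile (never silently).
Aggregation is the equal-weight mean over proteins, then summed within
organ systems; the organ grouping ships as a configuration table
(46 GTEx-style tissues over 11 systems) since any collapse of tissues
to systems is a reporting choice, not a property of the data. The
platform comparison divides organ probabilities; a zero-platform,
nonzero-exercise cell is flagged infinite rather than numeric.

This is probabilistic source attribution from transcript abundance
only — no secretion modeling, no deconvolution, no claim about physical
release routes.

## Trait simulation

Harmonization assumes both catalogs report the same strand, the
standard convention for summary-statistics work; palindromic A/T and
C/G pairs cannot be strand-resolved without allele frequencies and are
excluded by default (a flag includes them under the same-strand
assumption). The protein-raising allele a\* is the pQTL effect allele
when β_protein > 0, otherwise the other allele; the trait beta is
negated when the GWAS effect allele is not a\*. GWAS rows are kept at
p < 5×10⁻⁸, strictly. The sign rule maps (exercise direction, oriented
beta) to a simulated risk direction; a zero oriented beta is
indeterminate and excluded with a log message.

Concordance counts one vote per protein per trait — the majority
direction across its sentinel variants, ties excluded and logged —
because the clinical claim is about proteins, not variants. Which
direction counts as "beneficial" is configuration (lower coronary risk,
lower blood pressure), not code. The output is labeled a simulated
direction; no causal effect size is estimated.

The genetics generator plants the complete chain: per-protein cis/trans
sentinel assignment (55% cis, 16% both), deliberate allele-label flips
in half the GWAS rows, palindromic decoy variants with significant
trait rows, and per-trait beneficial counts (12/14 blood pressure,
6/15 coronary disease). Full recovery of the planted directions
through the pipeline therefore exercises every orientation branch.

## Problem sizes and determinism

The default synthetic study (1,305 × 48) runs end to end in ~1 s; the
test suite uses 120–600-protein studies for unit-level checks, the
full default for recovery checks (5 seeds), and 5 × 2,000 proteins for
null calibration. All randomness flows from `numpy.random.default_rng`
seeded per stream; rerunning any stage with the same seed reproduces
outputs bit for bit.

## What the benchmark does and does not show

Passing tests establish that the statistical machinery is correct and
that planted signal of realistic magnitude is recovered at the claimed
error rates under the generator's assumptions: log-normal signal,
homogeneous within-subject noise, no batch structure. Real aptamer data
additionally carry plate/batch effects, hemoconcentration after
exercise, aptamer cross-reactivity, heavy-tailed noise and
protein-specific variance structure, none of which the generator
emulates (the empirical-Bayes machinery is designed for exactly that
last feature, but the default benchmark, having homogeneous variances,
drives d₀ → ∞ and so exercises the full-shrinkage limit). The single
`frac_increasing` parameter also cannot reproduce per-intensity
asymmetries in the increase fraction seen in real data. Conclusions
about any real study must rest on that study's own data files, which
every stage accepts through the documented TSV/GCT/GMT formats.
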