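# Methods

This note documents the models, rules and numerical choices behind
`protshift`, and what the synthetic study conditions do and do not show.

## Study design being modelled

A two-arm (IP: high-protein supplement; CP: isocaloric comparator),
two-timepoint (T0 baseline, T12 after 12 weeks) randomised trial in subjects
with obesity, observed through stool shotgun metagenomes (a genes × samples
read-count matrix annotated to a reference catalog) and clinical outcomes
(weight, fat mass, visceral fat area, dietary intake).

## Gene- and MGS-level profiling

**Rarefaction (downsizing).** Gene richness depends on sequencing effort, so
counts are subsampled without replacement (multivariate hypergeometric) to a
common depth before richness is computed; per-gene counts and per-draw
richness are averaged over `n_draws` independent draws (default 30, the
common quantitative-metagenomics practice). Each sample consumes an independent seed stream derived from
the global seed and its own id, and genes are processed in a canonical sorted
order, so results are invariant to row/column order and to dropping other
samples. Richness is never computed on normalised values.

**Prevalence filter.** Features are retained when their nonzero prevalence
among baseline samples is *strictly* greater than the threshold (default
0.20): a feature present in exactly 20 % of baseline samples is excluded.

**MGS abundance.** An MGS (metagenomic species, > 500 genes by definition —
enforced) is quantified as the unweighted mean of the relative abundances of
all its designated marker genes. No trimming is applied: under the
simulator's uniform within-MGS gene weights the plain mean is unbiased, and
it is the simplest contract to test. An MGS is *present* when strictly more
than 10 % of its markers are detected (configurable); MGS richness is the
count of present species. MGS whose markers are covered below 50 % by the
gene table are dropped with a warning rather than estimated from a biased
subset.

**Richness response.** Subjects are classified *gained* / *lost* / *stable*
by the sign of their MGS-richness change; relative clinical change is
(T12 − T0)/T0 · 100. Stable subjects form their own class and are excluded
from gained-vs-lost contrasts. LGC/HGC strata split at the cohort median
baseline gene richness with ties assigned to HGC (`richness < median` defines
LGC); a fixed external threshold is supported where a published cut is to be
reused.

## Enterotyping (Dirichlet-multinomial mixture)

Genus-level counts are modelled as a K-component mixture of
Dirichlet-multinomials. EM alternates posterior responsibilities (E) with
weighted maximum likelihood of each component's Dirichlet vector via the
standard fixed-point update (M), which is an ascent step, so the
log-likelihood trace is non-decreasing (asserted in tests). Initialisation is
k-means on proportions; 5 restarts, relative tolerance 1e-6, α floored at
1e-10. Non-convergence within `max_iter` is flagged on the result, never
silent. Relative abundances are converted to counts by scaling with the
downsizing depth and rounding half-to-even (logged).

**Model selection.** The default criterion is a Laplace approximation of the
negative log evidence: the Hessian of each component's weighted likelihood in
log-α space is diagonal-plus-rank-one, so its determinant is analytic; the
mixture weights contribute their observed-information determinant on the
simplex (n^(K−1)/Ππ_k), which penalises near-empty components hard. A
component whose Hessian is not negative definite at the optimum falls back to
a BIC-style penalty on its effective sample size. BIC is available as an
alternative criterion. On pure two-component data the criterion selects K=2;
on the full hierarchical cohort (see below) larger K can legitimately win
because the compound model is overdispersed relative to a pure DM — the
assignment partition still matches the planted types (ARI ≥ 0.9).

**Labelling and switching.** Samples take the component with maximal
responsibility (ties → lowest index, logged); components are named by the
genus with the largest α proportion. Switch proportions (overall, by baseline
enterotype, by arm) are contrasted with two-sided Fisher exact tests — chosen
for the small counts involved; the test behind the original analysis is not
named in its report.

## Community statistics

Bray–Curtis BC(u,v) = Σ|u_i−v_i|/Σ(u_i+v_i); PCoA is classical scaling
(double-centre −D²/2, eigendecompose; negative eigenvalues are reported and
their axes dropped); PERMANOVA uses the pseudo-F from within/between summed
squared distances with p = (1 + #{F* ≥ F}) / (1 + n_perm), default 999
seeded permutations. Cliff's delta uses strict inequalities (ties count 0).
Log fold changes are natural-log subject-wise ratios with pseudocount
ε = half the smallest nonzero abundance in the table (configurable, recorded
in output headers via the `base` flag when a different base is requested).
The half-minimum rule keeps zero-to-detected transitions finite without
dominating the scale of genuine changes.

## Functional profiling

Modules are ordered steps, each a set of alternative KOs (one level of
alternatives; the full KEGG Boolean grammar is out of scope). Scoring per
sample: step abundance = sum of its alternatives' KO abundances; coverage =
fraction of steps detected; module abundance = median over **all** step
abundances (zeros included) if coverage ≥ 0.66, else 0 — the defaults of
rule-based module quantifiers; both the cutoff and the rule are configurable
because published analyses rarely state them. Genes annotated to several KOs
count fully toward each (logged; fractional splitting configurable).

Per-arm module dynamics classify by the sign of the mean log fold change;
exact zero is "unchanged" and excluded from proportions. The enrichment test
compares each arm's increased proportion to 0.5 (two-sided exact binomial)
and the arms to each other (chi-square on the 2×2 without continuity
correction, logged).

Completeness of module m in MGS g is the fraction of steps for which g's own
annotated gene set carries ≥ 1 alternative. Producer (synthesis) and degrader
guilds per amino acid collect MGS with completeness ≥ 0.66 by default —
surfaced prominently in `coverage_report` because degradation modules are
systematically sparsely annotated, so degrader guilds are less reliable than
producer guilds; the report flags degradation modules with no fully-complete
MGS.

**Planted-effect estimator.** Because compositions are renormalised after a
multiplicative boost, the raw producer-group fold change underestimates a
planted effect (closure bias). The package therefore estimates it as the
change in log2(producer / non-producer) abundance, contrasted IP − CP
(difference-in-differences), which is invariant to renormalisation and
unbiased to first order under the generator (the residual Jensen-type bias
from compositional jitter is ~2 % of the effect at the default conditions).

## Cohort statistics

Per-feature longitudinal effects use linear mixed models with a subject
random intercept, REML, and Wald tests on the time (pooled) or time×arm
(between-arm) coefficient, adjusted for baseline age, sex and BMI — the
covariate set stated with the original figure-level analyses. The Wald
statistic is referred to a t distribution with n_subjects − n_fixed degrees
of freedom: with two timepoints the coefficient has essentially that many
residual df, and the normal reference is measurably liberal at ~50 subjects
(≈ 5.6 % vs ≈ 5.3 % measured null rejection at α = 0.05). Adjusting
additionally for the feature's own baseline value is available
(`baseline_feature=True`) but off by default: with only two timepoints the
baseline duplicates the T0 response rows, which degrades the residual model
and the test's calibration. Satterthwaite-style degree-of-freedom corrections
are deliberately out of scope; at the default cohort size (50 subjects) the
Wald test's measured null rejection is ≈ 4–6 % at α = 0.05. Singular or
failed fits are flagged and excluded from the FDR family (one family per
scan, never pooled across feature types); BH-FDR threshold 0.1.

Clinical outcomes use a change-score linear model (change ~ arm + baseline +
age + sex + BMI, + centre when present) in place of the original stepwise
repeated-measures GEE: with two in-scope timepoints and no published
model-selection recipe, the stepwise procedure is not reproducible, while the
change-score model with the quoted covariate list estimates the same
between-arm contrast. Within-arm changes get paired t-tests; a Grubbs
pre-filter (two-sided, α = 0.05, iterated) is optional.

Richness–clinical associations are standardized betas (both sides z-scored)
from regressions of each clinical relative change on the richness change,
adjusted for the variable's baseline value, baseline BMI and sex, plus statin
intake for cholesterol/triglycerides when recorded. Module-fold-change /
clinical-change associations are Spearman correlations, BH-adjusted across
the whole matrix; constant vectors are reported missing and leave the family.

Dietary plausibility uses the original (1919) Harris–Benedict coefficients
(men: 66.473 + 13.7516 W + 5.0033 H − 6.755 A; women: 655.0955 + 9.5634 W +
1.8496 H − 4.6756 A); the Roza–Shizgal revision is behind a flag since
reports rarely state which was used. Records with 0.5·BMR ≤ intake ≤ 3·BMR
are retained (boundary kept — exclusion is for strictly implausible values);
missing anthropometry is reported separately from implausibility. Prescribed
intake is 1.3·BMR − 600 kcal per the intervention design; energy shares use
Atwater 4/9/4.

## The synthetic cohort

The generator emulates the trial at toy scale with known ground truth.
Defaults (the study conditions of every recovery test): 25 subjects per arm
(1:1, mirroring the ~50-subject microbiome subset of the original cohort),
40 MGS × 520 genes (30 markers), depth 100 000 reads, 2 enterotypes
(Bacteroides- and Prevotella-dominant) with concentration contrast 5, a
planted 1.0 log2FC on the producer pool in the IP arm at T12, richness
trajectory SD 15 % of baseline richness (the original study reports
per-stratum SDs of ~12–18 %), and weight change −3.3 kg on average with
−0.2 kg per gained species plus 1 kg noise; fat mass and visceral fat area
changes are linear in weight change with their own noise.

Generative model: each subject draws a profile θ from its enterotype's
Dirichlet component; T0 and T12 compositions are Dirichlet(κθ) jitter around
it (κ = 1000), reflecting the strong week-scale autocorrelation of gut
communities; richness churn adds/removes accessory MGS while dominant-genus
and guild MGS are treated as core (always present) — amino-acid guilds are
built from prevalent commensals, and this keeps module fold changes free of
absent-at-one-timepoint artefacts that a 40-species toy community would
otherwise magnify. Gene counts are multinomial at the configured depth with
uniform weights across an MGS's genes (markers unbiased). The producer pool
(25 % of MGS, one amino acid each so module dynamics stay decoupled) carries
complete synthesis modules; degraders (20 %) carry complete degradation
modules; non-members carry strictly incomplete random step subsets
(synthesis 5 %, degradation 2 % per step — degradation annotation sparser,
as in real repertoires). The planted boost multiplies producer MGS before
renormalisation, so the signal must survive the entire gene → KO → module
chain.

**What passing tests do not show.** The generator has no gene-length or GC
bias, no strain variation, no read-level errors, uniform within-MGS gene
weights, only two timepoints, and far fewer taxa and genes than a real
catalog (40 MGS vs ~10³, 2×10⁴ genes vs ~10⁷). Recovery and calibration
results therefore validate the pipeline's logic and statistics, not its
behaviour under mapping artefacts or real compositional complexity; absolute
power figures do not transfer to real cohorts.

## Problem sizes of the shipped analyses

The acceptance script and end-to-end tests use: 100 samples for DMM recovery
(K scanned over 1–3), 50 replicate cohorts for planted-shift recovery,
~1000 features for the null scan calibration, and 200 null cohorts for the
enrichment calibration — sizes at which the binomial/KS error of the
measured rates is small relative to the asserted bands.
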