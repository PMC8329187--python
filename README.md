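# protshift

Quantitative-metagenomics pipeline for two-arm dietary-intervention trials,
with a synthetic cohort generator that plants known effects so every stage of
the analysis has a recovery test.

The scientific setting: overweight subjects are randomised 1:1 to a
high-protein supplement (IP) or an isocaloric comparator (CP) on top of a
hypocaloric diet, with stool shotgun metagenomes and clinical outcomes at
baseline (T0) and week 12 (T12). The pipeline asks how the gut microbiome
responds: does species richness change and track clinical improvement, do
community types (enterotypes) switch, and does the extra protein shift the
community's amino-acid metabolic potential toward biosynthesis?

## What the package computes

- **Gene profiles** — rarefaction of the genes × samples count matrix to a
  common depth (without-replacement, multi-draw averaged), normalisation,
  gene richness, and the strict >20 % baseline-prevalence filter.
- **MGS profiles** — metagenomic species (MGS, >500-gene clusters) abundance
  as the mean of marker-gene relative abundances; presence (>10 % of markers
  detected); MGS richness; genus collapse; gained/lost/stable richness
  response with relative clinical changes (T12−T0)/T0·100; LGC/HGC strata.
- **Enterotyping** — Dirichlet-multinomial mixtures (DMM) fitted by EM on
  genus-level counts, exposed as a scikit-learn-style estimator
  (`DirichletMultinomialMixture`): for component k,
  x | z=k ~ DM(n, α_k), z ~ Categorical(π). Model selection by Laplace
  approximation of the evidence (BIC fallback), dominant-genus labelling, and
  longitudinal switch analysis with Fisher exact tests.
- **Community statistics** — Bray–Curtis dissimilarity
  BC(u,v) = Σ|u_i−v_i| / Σ(u_i+v_i), classical-scaling PCoA, PERMANOVA
  (pseudo-F, R², permutation p), Cliff's delta, and subject-wise
  log((T12+ε)/(T0+ε)) fold changes.
- **Functional profiles** — gene→KO collapse; module scoring (step = set of
  alternative KOs, step abundance = sum of alternatives, module called at
  step coverage ≥ 0.66, abundance = median over steps, zeros included);
  per-arm increase/decrease classification with exact binomial tests vs 0.5
  and a between-arm chi-square; MGS × module completeness; amino-acid
  producer/degrader guilds and their summed abundances.
- **Cohort statistics** — per-feature linear mixed models (subject random
  intercept, time and time×arm effects, baseline age/sex/BMI adjustment)
  with Benjamini–Hochberg FDR at 0.1; Grubbs outlier detection; adjusted
  between-arm change contrasts; standardized richness–clinical regressions;
  Spearman fold-change/clinical correlation matrices; Harris–Benedict
  dietary-plausibility screening (retain 0.5·BMR ≤ intake ≤ 3·BMR, prescribed
  intake 1.3·BMR − 600 kcal).
- **Synthetic cohort** — `SimulationConfig`/`generate_catalog`/
  `generate_cohort` build a toy catalog, paired cohort and ground truth with
  planted enterotypes, richness trajectories linked to clinical change, and
  an IP-arm amino-acid-synthesis shift.

## Worked example

```python
from protshift import (SimulationConfig, enrichment_proportion_test,
                       planted_effect_estimate)
from protshift.pipeline import simulate_and_profile

res = simulate_and_profile(SimulationConfig(seed=1))
truth = res["cohort"].truth
enr = enrichment_proportion_test(res["dynamics"], res["modules"], "aa_synthesis")
print(enr[["arm", "n_increased", "n_classified", "prop_increased", "binomial_p"]])
est = planted_effect_estimate(res["mgs"], truth.producer_pool,
                              res["pairs"], res["arms"])
print(f"planted log2FC estimate: {est:.2f}")
```

prints

```
  arm  n_increased  n_classified  prop_increased  binomial_p
0  CP            6            10             0.6    0.753906
1  IP            9            10             0.9    0.021484
planted log2FC estimate: 1.01
```

The cohort plants a 1.0 log2 fold change on amino-acid-producer MGS in the
IP arm at week 12: 9 of 10 synthesis modules are classified as increased in
the IP arm (exact binomial p = 0.021 against the coin-flip null) versus 6 of
10 in CP, and the closure-corrected producer-group estimate recovers the
planted effect (1.01 here; unbiased over replicates).

A command-line interface mirrors the library
(`protshift simulate|genes|mgs|enterotype|beta|dynamics|func|stats`), e.g.

```bash
protshift simulate --out cohort/ --seed 1
protshift func ko cohort/gene_counts.tsv --map cohort/gene_to_ko.tsv --out kos.tsv
```

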