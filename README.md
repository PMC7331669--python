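# exprot

Analysis of intensity-dependent plasma-proteome responses to acute
exercise.

A single bout of running perturbs hundreds of circulating proteins, and
the response depends strongly on exercise intensity. `exprot` implements
the full analysis chain for a paired two-intensity study design — the
same subjects run once at moderate and once at high intensity, with
blood drawn immediately before and after each bout and a fixed aptamer
panel quantifying relative plasma protein abundance:

1. **Paired differential abundance** per intensity with empirical-Bayes
   variance moderation and Benjamini–Hochberg FDR control.
2. **Cross-intensity partitioning** of responders (moderate-only /
   high-only / shared), directional concordance checks, and a
   dose-dependence classification of shared responders.
3. **Gene-set overrepresentation** of up-regulated proteins (binomial
   test, fold enrichment, Bonferroni).
4. **Tissue-source inference**: probabilistic mapping of increased
   proteins to donor tissues from transcript abundance, aggregated by
   organ system and compared against the whole-platform profile.
5. **pQTL/GWAS trait simulation**: harmonize trait effect sizes to the
   protein-raising allele and simulate the direction of each protein's
   exercise response on genetically linked traits.
6. A **synthetic-data generator** that produces complete studies with
   planted ground truth (responsive sets, dependence classes, allele
   flips, trait directions), so every stage is testable end to end.

It is intended for computational biologists studying exercise physiology
or, more generally, paired pre/post omics designs with a dose factor.

## The statistics at the core

For protein *g*, subject *s* and one intensity, the paired log-ratio is
*d*₍g,s₎ = log₂(post/pre). With per-protein sample variance *s*²_g on
*d*_g (df *d*_g = n−1), variances are shrunk toward a prior estimated by
the method of moments on log *s*²_g (under a scaled inverse-χ² prior,
*s*²_g/*s*₀² ~ F(*d*_g, *d*₀)):

```
s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)
t̃_g  = mean(d_g) / (s̃_g / √n),   t̃_g ~ t(d₀ + d_g)
```

Two-sided p-values are BH-adjusted within each intensity; q < 0.05 is
called significant. Shared responders with fold changes FC_M and FC_H
are classified with the magnitude ratio *r* (FC_H/FC_M for increasing,
FC_M/FC_H for decreasing proteins): *r* ≥ 1.25 is intensity-dependent,
|FC_H − FC_M|/FC_M ≤ 0.05 intensity-independent, otherwise intermediate.

Tissue-source probabilities follow the TPM share of each tissue,
p(tissue a) = TPM_a / Σ_j TPM_j, averaged with equal protein weights and
summed within organ systems. Trait directions use the sign rule on the
trait beta oriented to the protein-raising pQTL allele; palindromic
variants are excluded as strand-ambiguous.

## Worked example

```python
from exprot import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(out_dir="exprot_demo", seed=1))
print(report.partition)
print(report.trait_concordance)
```

prints

```
{'moderate_only': 29, 'high_only': 448, 'shared': 168,
 'moderate_total': 197, 'high_total': 616, 'union': 645}
{'blood_pressure': [12, 14], 'coronary_artery_disease': [6, 15]}
```

meaning: 645 of 1,305 proteins (49%) respond to exercise at q < 0.05;
197 at moderate and 616 at high intensity, 168 at both — roughly a
three-fold expansion of the responsive proteome at high intensity. Of
the trait-linked responders, 12 of 14 blood-pressure proteins move in a
direction consistent with lower blood pressure (matching the planted
truth exactly), while coronary-disease proteins split 6 of 15 toward
benefit. Each numbered script in `examples/` walks one stage with a
small input and prints what it computes; the `exprot` console command
(`simulate`, `diff`, `classify`, `enrich`, `tissues`, `traits`, `run`)
exposes the same stages from the shell.

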