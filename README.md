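# bioturb

Quantifying how exogenous inoculation ("bioturbation") restructures the
indigenous microbiota of a fermentation starter — and how that
restructuring relates to the starter's enzymatic function.

Medium-temperature *Daqu*, the spontaneously fermented wheat starter
used in Baijiu production, is often fortified by inoculating functional
*Bacillus* isolates. `bioturb` implements the statistical pipeline for
asking *which* members of the indigenous community respond to the
inoculation rather than to the fermentation process itself, and *how*
the responders relate to the starter's liquefying (LA), saccharifying
(SA), esterifying (EA) and fermenting (FA) activities. It is aimed at
microbiome researchers analysing amplicon (ASV) count tables from
designed fermentation experiments.

## The analysis

Given per-kingdom ASV × sample count tables and sample metadata
(treatment arm DD/CD/PD, day, fermentation parameters, activities), the
pipeline classifies every ASV through a cascade:

* **pASV** — parameter-driven: the community passes a Mantel gate
  (p < 0.05) for a fermentation parameter, and the ASV passes a Spearman
  screen |ρ| > 0.60, p < 0.05 against it;
* **iASV** — indicator ASV for one or more arms: IndVal over group
  combinations, stat = √(A·B) with group-size-corrected specificity A and
  occurrence fidelity B, permutation p < 0.05;
* **brASV** = iASV \ pASV — associated with the inoculation, not the
  process;
* **bsASV** = brASV ∩ {negative-binomial GLM likelihood-ratio test,
  TMM offsets, BH-FDR < 0.05} — responding *significantly*;
* **eASV** — activity-linked: maximal information coefficient
  MIC ≥ 0.35 (strong at ≥ 0.55), capturing linear *and* nonlinear links.

On top of the cascade it computes the bioturbation **effect size**
(share of sequences carried by bsASVs), positive co-occurrence networks
(Spearman ρ > 0.65, p < 0.001) with greedy-modularity modules,
**bsModules** (top-10 modules holding ≥ 10% of bsASV nodes), per-activity
**effect intensity** (share of eASVs that are bsASVs) and eASV coverage
by bsModules. TMM/CPM normalization, IndVal, the NB-LRT with Cox–Reid
common dispersion, and the MINE/ApproxMaxMI MIC estimator are all
implemented in the package and validated against independent oracles
(edgeR, statsmodels, scikit-bio, exhaustive enumeration).

A synthetic-data generator reproduces the study design (3 arms × 10
sampling days × 3 replicates, three-phase temperature profile,
compositional counts at ~80k reads) with planted parameter-driven,
treatment-responsive and enzyme-linked taxa, and returns the ground
truth so the whole pipeline is testable by recovery.

## Worked example

```python
from bioturb import BioturbationAnalysis

model, truths = BioturbationAnalysis.from_synthetic(seed=1, bacteria_only=True)
results = model.fit()
print(results.summary())
```

prints:

```
Bioturbation response analysis (bioturb 0.1.0)
config hash 16682e8cd250, seed 1
samples: 90

[bacteria]
  pASV: 215   iASV: 40   brASV: 39   bsASV: 29 {'CD': 18, 'DD': 20, 'PD': 20}
  common dispersion: 1.3885   differential (FDR<0.05): 65
  bioturbation effect size: 2.12% of sequences

eASV counts (MIC>=0.35): {'LA': 18, 'SA': 20, 'EA': 16, 'FA': 10}
strong eASV (MIC>=0.55): {'LA': 6, 'SA': 7, 'EA': 6, 'FA': 5}

modules: {'CD': 171, 'DD': 163, 'PD': 166, 'all': 173}
bsModules (top 10, share>=0.1): [8]
effect intensity (bsASV share of eASVs): {'LA': '22.22%', 'SA': '15.00%', 'EA': '12.50%', 'FA': '20.00%'}
eASV coverage by bsModules: {'LA': '5.6%', 'SA': '0.0%', 'EA': '6.2%', 'FA': '0.0%'}
```

Reading the output: 29 of the 500 synthetic taxa are classified as
responding significantly to the inoculation (the generator planted 30;
an ASV indicating a pair of arms is listed under both, so the per-arm
counts exceed the union); the responders carry 2.12% of all sequence
counts; one of the ten largest co-occurrence modules concentrates
enough responders to count as bioturbation-sensitive; and a fifth of
the LA-linked taxa are themselves responders — the planted overlap
between responsive and activity-linked taxa is the pattern the
analysis is designed to expose.
`results.classification_frame()` gives the per-ASV table,
`results.save(outdir)` writes all result TSVs, and
`results.plot_degree_abundance()` draws the degree-vs-abundance view
with responders highlighted.

The same pipeline runs from the shell:

```
bioturb simulate --seed 1 --outdir study/
bioturb classify --counts bacteria study/counts.tsv --meta study/metadata.tsv \
    --seed 1 --outdir study/results/
bioturb run-all --seed 1 --outdir study/   # simulate + full cascade + report
```

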