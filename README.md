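# uvbclines

Geographic distribution of vitamin D-pathway allele frequencies across
continental ancestry groups.

`uvbclines` is a small analysis pipeline for a recurring question in human
population genetics: do allele frequencies of variants in vitamin D-related
genes (*DHCR7/NADSYN1*, *GC*, *CYP2R1*, *CYP11A1*, *CYP24A1*, *CYP27A1*,
*VDR*, *RXRα*, *RXRγ*) track the long-term UVB environment of a population's
ancestry, the way skin-pigmentation loci do? It is written for researchers
who assemble per-cohort variant-allele frequencies from public resources
(ALFRED-style frequency tables, 1000 Genomes VCFs) and want a reproducible,
tested path from those tables to per-variant distribution patterns and
UVB-cline calls.

## What it computes

The unit of analysis is the **sample set** (one population cohort with
subject count *n*, a geographic group label EUR/EAS/AFR, and coordinates).
For each variant, with per-set frequency $y_i$, weight $w_i = n_i$ and group
means $\bar y_g$:

* **Fixation-index ranking.** Variants are ranked by differentiation using
  Wright's index $F_{ST} = \operatorname{Var}_w(p_i) / \bar p(1-\bar p)$
  (or the Weir–Cockerham 1984 variance-components estimator $a/(a+b+c)$ for
  genotype input), and selected by a top-fraction rule with an $F_{ST}$
  floor (defaults: top 30 %, $F_{ST} \ge 0.13$), dropping variants of
  unknown functional class.
* **Ancestry validation.** Cohort-weighted group means of three
  pigmentation markers (SLC24A5 rs1426654, SLC45A2 rs16891982, OCA2
  rs1800414) must fall in their expected windows (near-fixed in EUR /
  near-absent elsewhere; EAS-restricted at 0.50–0.65) before any
  frequency comparison runs.
* **Weighted group comparison.** A cohort-size-weighted one-way ANOVA
  (identical to WLS on group indicators) gives the association *p* and
  adjusted $r^2$; Tukey–Kramer studentized-range tests give the three
  pairwise *p* values; Bonferroni-adjusted thresholds (*p* < 0.001
  association, *p* < 0.0001 pairwise) flag significance; a compact letter
  display encodes which groups are indistinguishable.
* **UVB environment.** Daily noontime 305 nm surface irradiance on a
  half-degree grid is averaged over the cells covering each sample-set
  location, then compared between groups with the same weighted machinery.
* **Classification.** The three pairwise flags map to a distribution
  pattern (`EUR!=AFR!=EAS`, `EUR!=AFR and EAS`, …, `NONE`), and group means
  are checked for strict monotonicity along ascending group UVB to label
  each variant `INCREASING`, `DECREASING` or `NONE`.

A Balding–Nichols synthetic generator (per-set frequencies drawn from
$\mathrm{Beta}(p\frac{1-\theta}{\theta},\,(1-p)\frac{1-\theta}{\theta})$
around group means $p$, plus a latitude-gradient UVB raster) reproduces the
built-in reference design — 60 cohorts (18 EUR / 24 EAS / 18 AFR; 972, 795
and 866 subjects) and a 46-variant panel — so the entire pipeline runs and
is tested without any downloads.

## Worked example

Simulate the reference design and run the full pipeline:

```sh
uvbclines simulate --out-dir demo --seed 1
uvbclines uvb --sets demo/sample_sets.tsv --raster demo/uvb_raster.csv --out demo/uvb.tsv
uvbclines compare --freq demo/frequencies.tsv --sets demo/sample_sets.tsv \
    --annotations demo/annotations.tsv --out demo/report.tsv
```

The UVB step prints the per-group mean annual irradiance and the Tukey
pairwise comparisons:

```
group means: EUR=19.7, EAS=45.7, AFR=81.8 (ascending: EUR < EAS < AFR)
  EUR vs EAS: p = 2.17e-11
  EUR vs AFR: p = 0.00e+00
  EAS vs AFR: p = 0.00e+00
```

i.e. equatorial AFR locations receive the most 305 nm irradiance
(81.8 Mw/m²/nm), northern EUR locations the least (19.7), and all pairwise
differences are significant. `demo/report.tsv` then holds one row per
variant; for instance the DHCR7/NADSYN1 variant rs7944926 comes out as

```
rsid        mean_EUR  mean_EAS  mean_AFR  p_assoc   pattern         uvb_cline
rs7944926   0.29      0.61      0.86      2.18e-33  EUR!=AFR!=EAS   INCREASING
```

— its frequency differs between all three groups and rises monotonically
with ancestral UVB, while e.g. rs12280295 is `AFR!=EUR and EAS` (present
only in AFR), a population-specific pattern with no UVB cline.

The same stages are importable (`uvbclines.analyze_variants`,
`uvbclines.run_pipeline`, …) for use from Python, and `uvbclines run
--config cfg.yaml` executes everything from one YAML file, writing the
report plus a JSON manifest of input checksums, thresholds and per-stage
record counts.

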