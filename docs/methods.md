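# Methods

## Data model and units

The unit of analysis throughout is the *sample set*: one population cohort
with a subject count *n*, a geographic ancestry group (EUR, EAS, AFR), and a
location given as a longitude plus a latitude point or range (southern
latitudes negative). Frequencies are variant-allele proportions in [0, 1],
already oriented to the panel's variant allele — the package deliberately
does not attempt strand or allele reconciliation between frequency databases
and VCF sources; the input contract is that the frequency table is oriented
to the annotated variant allele. Genotype (VCF) input is a secondary mode:
biallelic diploid GT fields are tallied to hom-ref/het/hom-alt per set and
collapsed to frequencies as (2·hom_alt + het)/2n; multiallelic records are
skipped with a warning and missing calls are excluded per variant.

## Differentiation estimators and variant selection

Two fixation-index estimators are provided:

* `wright_fst` — Wright's frequency-variance form, the population-weighted
  variance of subpopulation frequencies over p̄(1−p̄), clamped to [0, 1] and
  defined as 0 on monomorphic input. This is the default for frequency-table
  input because frequency databases supply frequencies, not genotypes.
* `weir_cockerham_fst` — the 1984 variance-components estimator a/(a+b+c)
  from per-population genotype counts, for VCF mode. Being nearly unbiased it
  can go negative on undifferentiated data; negative estimates are reported
  as 0 (the raw value goes to the debug log).

Selection ranks variants by fixation index (precomputed indices in the
annotation table take precedence, mirroring database-supplied values, with
on-the-fly computation as fallback), keeps the top fraction (default 0.30)
that also clears a floor (default 0.13), then drops excluded function
classes (default: unknown functional consequences). Rank ties at the
boundary are broken by rsid lexicographic order, making the output invariant
to input order. Both "FST across all sample sets" and "FST across group
means" modes exist (`fst_from_frequency_matrix(by_group=...)`), since either
convention is defensible for database-derived indices.

## Ancestry validation

Before any comparison, cohort-weighted group means of three pigmentation
markers must fall in their expected windows: rs1426654 and rs16891982 ≥ 0.90
in EUR and ≤ 0.10 in EAS/AFR; rs1800414 in [0.50, 0.65] in EAS and ≤ 0.10
elsewhere. (The EUR bound is a *minimum*: markers described as "fixed" in
Europeans are expected near 1, and the windows are configurable.) Sample
sets lacking data for any validation marker are excluded from all downstream
analysis. The pipeline aborts on a failed window by default; a flag
continues with a warning.

One honest wrinkle of the reference design: the expected EUR mean of
rs16891982 (0.91) sits only ~0.5 resampling standard deviations above its
own 0.90 bar, so under the default generator dispersion (θ = 0.02) roughly a
third of seeds produce a simulated collection that legitimately fails this
rule and aborts. That is the validation gate working as specified, not a
generator defect; the bundled seeds used in tests pass all rules.

## Weighted group comparison

For one variant with per-set frequency y_i, weight w_i = n_i and k groups:

    SSB = Σ_g W_g (ȳ_g − ȳ)²,   SSW = Σ_i w_i (y_i − ȳ_g(i))²,
    F = (SSB/(k−1)) / (SSW/(N−k)),   r² = SSB/(SSB+SSW),
    adj r² = 1 − (1−r²)(N−1)/(N−k)

which is algebraically identical to weighted least squares on group
indicator variables (asserted to 1e-10 against statsmodels WLS in the test
suite). All statistics are invariant to permuting sets and to rescaling all
weights by a positive constant. Degenerate inputs: SSW = 0 with SSB > 0 is
perfect separation (p reported as 0 and flagged); SSB = SSW = 0 gives F = 0,
p = 1. Near-zero sums of squares are snapped to zero at a relative tolerance
of 1e-12 of the weighted sum of squares so constant inputs do not produce
ratios of rounding noise.

Group CIs are model-based, from the pooled within-group mean square:
mean_g ± t(df_within, 0.975)·√(MSW/W_g). Because the interval uses pooled
spread rather than the group's own range, bounds are deliberately not
clamped to [0, 1] — a group pinned at frequency 0 gets a symmetric interval
crossing zero. The CI is covered by shape tests (symmetry, bracketing,
monotone widening in the level), not by matching any particular printed
width, since the variance scaling convention of weighted intervals is not
standardized across software.

Tukey–Kramer pairwise p values use the studentized range distribution
(scipy.stats.studentized_range, which integrates the range CDF numerically)
with q_ij = |ȳ_i − ȳ_j| / √((MSW/2)(1/W_i + 1/W_j)); for k = 2 this reduces
exactly to the two-sided pooled t-test (q = t√2), and the balanced
unweighted case is cross-checked against statsmodels' Tukey HSD to 1e-4.
Significance uses Bonferroni-adjusted thresholds with *strict* inequality:
association p < 0.001, pairwise p < 0.0001, both configurable.

The compact letter display uses the insert-and-absorb algorithm over the
fixed group order (EUR, EAS, AFR): start from one letter containing all
groups; for each significant pair split every letter set containing both;
dedupe and absorb subsets. For k = 3 this is exact — two groups share a
letter iff their pairwise p ≥ α — and the property is tested on random p
matrices.

## UVB aggregation

Rasters are half-degree cells addressed by center, holding dated daily
noontime 305 nm irradiance (Mw/m²/nm). A point location belongs to the cell
whose center is nearest, with boundary points assigned north/east (so a
point at 43.0° falls in the cell centered 43.25°). A latitude-range location
takes all cells at the set's longitude whose centers lie in the closed range
(default), or the single midpoint cell (`range_mode="midpoint"`); both modes
are recorded in the output because the right convention for range-located
cohorts is genuinely ambiguous. Mean annual UVB is the plain arithmetic mean
over all selected cells and days — linear in the raster and order-invariant.
Sets without coordinates are excluded from UVB aggregation only, never from
frequency statistics. Group UVB comparison reuses the weighted ANOVA /
Tukey machinery with per-set mean UVB as the response.

## Synthetic generator

The generator exists so that every stage runs and is tested without network
access, and so that statistical properties have analytic targets.

* **Frequencies** follow the Balding–Nichols model: within a group with mean
  p, each set's latent frequency is Beta(p(1−θ)/θ, (1−p)(1−θ)/θ), giving
  mean p and variance θ·p(1−p); θ is the drift parameter and equals the
  expected Wright index of sets around their group mean. θ below 1e-9 or p
  in {0, 1} are degenerate: the latent frequency is exactly p. Observed
  frequencies default to the latent values (analytic checks stay exact);
  binomial resampling of 2n alleles is available behind a flag.
* **Default θ = 0.02** — a realistic magnitude of within-continent
  differentiation for human cohort collections, used for the reference
  simulation throughout; the null-calibration suite uses θ = 0.05 with
  equal cohort sizes (with weights equal the weighted F is exactly the
  classical F; the latent variance does not scale with n, so unequal
  weights would deliberately misspecify the null).
* **Reference design.** The bundled roster reproduces the published
  60-cohort design exactly: 18 EUR, 24 EAS and 18 AFR sample sets with their
  cohort sizes (972/795/866 subjects, 2633 total) and latitudes; group mean
  frequencies for the 16 production/transport variants and the 3
  pigmentation markers are the published values. Longitudes are not part of
  the published roster and are hand-assigned representative values (the
  synthetic raster depends on |latitude| only, so they affect nothing
  statistical).
* **UVB raster**: daily value at cell latitude L is
  max(0, base − decay·|L|) + N(0, sd), clamped at 0, one value per day. The
  defaults (base 94.0 Mw/m²/nm, decay 1.45 per degree, sd 5.0, 365 days)
  were fitted once to place the three reference groups near the published
  mean annual levels (~82 / ~48 / ~18 Mw/m²/nm for AFR/EAS/EUR) and are not
  revisited; a single synthetic year stands in for the satellite record's
  multi-year span since only the mean enters any statistic.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: within-group substructure (θ is one scalar per
collection, although real collections mix e.g. several Italian and Han
cohorts), linkage between variants (columns are independent), seasonality
and cloud/ozone structure in UVB, and sampling error of database frequency
estimates unless binomial mode is enabled.

## Pattern and cline classification

The three pairwise significance flags map exhaustively onto six labels: all
three significant → all groups differ; exactly two → the group common to
both significant pairs differs from the other two; exactly one → PARTIAL (a
configuration the published footnote taxonomy never needed, named rather
than forced into another label); none → NONE. The UVB cline uses point
estimates only: group means strictly monotone along ascending group UVB
(EUR < EAS < AFR in the reference design, or an ordering derived from the
raster at run time) give INCREASING/DECREASING; ties or non-monotone
orderings give NONE. No per-variant trend test is applied — the cline label
is descriptive, matching how such gradients are discussed in this
literature.

## Determinism and problem sizes

Every stochastic path is driven by one integer seed (the raster stream is
decoupled from the frequency stream so adding variants does not perturb
UVB values). Fixed seed ⇒ byte-identical simulated inputs, reports and
manifests. The default test suite and the acceptance script use the 60-set
reference design, 2000-replicate null calibration and 11 seeded
pattern-recovery replicates — sizes chosen so the full run completes in
well under a minute on one CPU while keeping Monte-Carlo noise far from the
asserted bands.

## Known limitations

* Printed p/r² values from the original frequency compilations cannot be
  re-derived without the raw per-set frequencies; the package's acceptance
  surface is therefore design bookkeeping, estimator oracles, calibration
  and pattern recovery, not numeric table reproduction.
* The CI variance convention (pooled MSW on the weighted scale) is one of
  several defensible choices; interval *shapes* are tested, widths are not
  comparable across software.
* `PARTIAL` patterns and two-group collections are supported by the engine
  but exercised only by unit tests, not by the reference design.
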