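# Methods

`reefexo` implements the downstream analysis of benthic primary-producer
exometabolomes from aligned untargeted LC-MS/MS feature tables: a
rule-based classification cascade, enrichment statistics, carbon-weighted
energetics, abundance-weighted elemental stoichiometry, ordination, and
molecular-family (subnetwork) analyses — together with a synthetic
experiment generator that plants ground truth so every stage is testable
without any external data.

## Experimental design assumed

Triplicate specimens of five benthic producers — the corals *Porites* and
*Pocillopora*, crustose coralline algae (CCA), the macroalga *Dictyota*,
and mixed turf algae — incubated in filtered reef water over an 8-h
daytime and an 8-h nighttime period, alongside producer-free Control
incubations; ambient (starting) reef water sampled in triplicate per diel
period; eight process blanks. That is 42 experimental samples plus 8
blanks. The cascade itself runs on whatever sample set matches this
role/treatment/diel/timepoint vocabulary; replicate counts >= 2 per
endpoint cell are required for the grouped tests.

## The classification cascade

Stages run in fixed order on XIC peak areas (gap-filled zeros are data,
not missing values):

1. **Background**: mean over all non-blank samples < 2 x the maximum over
   blanks. Removed.
2. **Transient**: at or above the detection threshold (2e5, double the
   1e5 instrument noise floor) in fewer than 3 experimental samples.
   Removed.
3. **Ambient vs exudate**: a feature is an exudate if
   log2(mean endpoint cell / mean ambient start) > 1 in any
   (treatment, diel) endpoint cell, Controls included. Both means are
   floored at the noise threshold (1e5) first, so an empty ambient
   baseline yields a finite, conservative ratio rather than infinity.
   The flooring rule is a package choice; it preserves the "at least
   doubled" semantics at realistic intensities.
4. **Exometabolite**: exudate features significantly enriched in >= 1
   producer endpoint relative to the Control endpoint of the same diel
   period. Per diel period the six endpoint groups form a pooled-variance
   one-way layout; each producer is compared to the Control with
   Dunnett's many-to-one statistic, one-sided (producer > Control)
   because the definition is enrichment (two-sided available by option).
   The Dunnett-adjusted p-values are then Benjamini–Hochberg corrected
   over the pooled family of all features x 5 producers x 2 diel periods
   — the most conservative defensible family; a per-diel family is
   available by option. The test runs on per-sample relative abundances
   (shares of total feature peak area) by default, raw areas by option.
   The omnibus ANOVA F is computed and reported but does not gate the
   Dunnett comparisons by default (gating by option).
5. **Subtypes** (non-exometabolite exudates): *incubation artifact* if
   doubled vs ambient in both Day and Night Controls (dropped from
   downstream summaries); else *benthic exudate* if doubled in >= 1
   producer incubation; else *planktonic exudate* if doubled in either
   Control. Precedence artifact > benthic > planktonic: the classes are
   exclusive, and producer origin takes priority over Control origin for
   features doubled in both. The subtype "doubled" test reuses the
   stage-3 floor rule.

Count conservation holds by construction: background + transient +
ambient + exudate = all features; exometabolite + benthic + planktonic +
artifact = exudate.

## Statistics

All procedures are implemented in `reefexo.stats` from first principles,
with scipy supplying only univariate reference distributions and
quadrature nodes.

**Dunnett many-to-one.** t_i = (mean_i − mean_0)/sqrt(MSE(1/n_i + 1/n_0))
with MSE pooled over all groups. Under H0 the statistic vector follows a
multivariate t with correlation rho_ij = b_i b_j, b_i =
sqrt(n_i/(n_i+n_0)), from the shared control term. Conditional on the
control z-score and the pooled-SD scale the joint CDF factorizes, leaving
a smooth 2-D integral evaluated by product Gauss quadrature —
Gauss–Hermite for the control term and generalized Gauss–Laguerre for the
chi-distributed scale (Gauss–Legendre in chi-probability space below 8
df, where Laguerre converges slowly). The evaluation is fully
deterministic (no RNG) with absolute error around 1e-9 at the designs
used here, verified in the tests against both an independent
quasi-Monte-Carlo implementation and a 10^6-draw max-T simulation. With
one comparison the statistic reduces exactly to a pooled two-sample t and
is shortcut to the analytic t distribution. Large batches reuse a cached
4096-point interpolation grid on t in [-12, 12] (interpolation error far
below 1e-4; |t| > 12 falls back to direct evaluation).

**Tukey HSD** uses the studentized-range distribution with the
Tukey–Kramer standard error. The compact letter display assigns one
letter per maximal clique of the non-significance graph (alpha = 0.05).
Connected components were considered and rejected: a chain a–b, b–c of
non-significant pairs with a–c significant would merge all three under a
component rule; the clique cover is the standard display and preserves
every significant separation.

**BH FDR** is the classical step-up transform, monotone and capped at 1.

**Ordination**: per-feature relative abundances are arcsine-square-root
transformed and z-scored per feature; samples are ordinated by principal
coordinates (Gower double-centering + eigendecomposition) of Euclidean
distances on the transformed matrix, which makes the PCoA a PCA of that
matrix. Negative eigenvalues are reported, not corrected. The distance
metric is a package choice; the transform makes Euclidean natural.

**PERMANOVA** partitions the Gower-centered distance matrix by sequential
(Type I) sums of squares in the fixed order treatment, diel,
treatment x diel, with pseudo-F and free permutation of sample labels
(seeded generator, >= 99 permutations; p = (exceedances+1)/(n_perm+1)).
Permutations that exactly reproduce the observed statistic (possible with
duplicated points) count as exceedances, so the attainable minimum p can
be above 1/(n_perm+1) on degenerate input. Pairwise one-way contrasts
report raw and BH-adjusted permutation p, since no single correction
convention dominates for a-posteriori contrasts.

**Congruency** between two categorical labelings is Theil's uncertainty
coefficient U(category | label) = G^2 / (2 N H(category)), with G^2 the
likelihood-ratio statistic of the contingency table and H the natural-log
entropy of the category margin — the "RSquare (U)" of common
contingency-analysis software, 1 when the label determines the category
and 0 under independence. The chi-square p uses the LR statistic;
Cramér's V is reported as an alternative effect size.

## Energetics and stoichiometry

The nominal oxidation state of carbon of a CHNOPS formula with counts
(a=C, b=H, c=N, d=O, e=P, f=S) and net charge Z is
`NOSC = 4 − (−Z + 4a + b − 3c − 2d + 5e − 2f)/a`, −4 for methane through
0 for sugars to +4 for CO2. The standard Gibbs energy of the
carbon-oxidation half reaction at 298 K is the affine relation
`dG_cox = 60.3 − 28.5 · NOSC` kJ (mol C)^-1 (LaRowe & Van Cappellen
2011); both constants are config-exposed. Lower NOSC (more reduced
carbon) means more catabolic energy.

Formulas enter these computations only if their assignment is high
quality: ZODIAC score > 0.98, non-chimeric consensus spectrum, best
fragmentation tree explaining > 4 fragments and > 80% of spectral
intensity. Elements outside CHNOPS flag the record and exclude it from
NOSC.

Per producer endpoint sample, over that producer's exometabolite features
(daytime cells by default) with quality-passing formulas:

* **weighted NOSC** uses carbon-content weights, w_i = abundance_i x C_i,
  as the energetics convention requires;
* **elemental ratios** (N:C, P:C, H:C, O:C) are abundance-weighted means
  of the per-molecule ratios ("per molecule" convention); the
  alternative ratio-of-weighted-element-sums is deliberately not the
  default — the two rules differ and the difference is intentional;
* **ternary classes** partition molecules into P-containing, N-without-P,
  and CHO(S)-only, with abundance-weighted shares summing to 1.

A robustness variant replaces abundance weights with per-feature z-scores
of peak area (shifted by the within-sample minimum to keep weights
non-negative, since weighted means require non-negative weights),
removing among-feature ionization differences. When every z-profile
coincides in a sample the weights collapse and the variant falls back to
equal weights (the unweighted mean).

## Subnetwork analyses

Features sharing a molecular-family id (from spectral networking,
consumed as annotation) are aggregated by summing member relative
abundances per sample; singletons are excluded but accounted for in the
conservation identity. Enrichment per (producer, diel) uses the same
Dunnett + pooled BH machinery on the summed shares (raw-area mode by
option) with a conjunction rule: adjusted p < 0.05 AND fold >= 2 vs the
Control mean. Focus networks additionally require mean summed share
> 0.05% of at least one producer's exometabolome (per-treatment mean over
endpoint replicates) and more than five exudate nodes. Consensus
structural class per subnetwork is the majority class among annotated
members, ties mapping to "unclassified".

## Bulk chemistry

Endpoint concentrations (DO, pH, DOC, nutrients) are compared across the
six groups per diel period by one-way ANOVA with BH FDR across analytes
within the diel period (matching how such panels are presented), followed
by two-sided Dunnett comparisons vs Control. A delta mode subtracts the
diel-matched ambient-start mean first; endpoint mode is the default. DOC
is regressed on the per-sample summed exudate-feature peak area and,
separately, on the summed ambient-feature peak area, per diel period;
weighted N:C and P:C are regressed on TDN and TDP over matched samples.

## The synthetic experiment generator

The generator emulates the study design above with seven planted feature
classes (defaults in parentheses): background (150), transient (100),
ambient (300), exometabolite (250), benthic exudate (150), planktonic
exudate (80), incubation artifact (40).

* **Noise**: mean-preserving multiplicative lognormal on the expected
  intensity (sigma = 0.3 in natural log, CV ≈ 31% — a typical
  between-replicate spread for XIC areas of biological triplicates; the
  within-treatment variance is a free parameter of the generator, chosen
  once) plus a small additive detector term (SD 2e3), truncated at zero.
* **Exometabolites** are enriched in the endpoint cells of 1–5 source
  producers (86% exactly one, mirroring the strong producer specificity
  the method is meant to resolve) with lognormal fold changes of median
  40 and geometric SD 5, truncated to [5, 150]: below ~5-fold a 3-vs-3
  comparison has essentially no power and the feature would be
  indistinguishable from the benthic class by construction; above ~150
  a single feature dominates every weighted summary. Diel activity is
  day-only/night-only/both at 0.6/0.1/0.3. A per-producer exudation
  scale (Turf 1.6 ... Porites 0.5) mirrors the rank order of DOC release
  across producers.
* **Benthic exudates** are enriched 4.5–8x in one producer, but the
  enrichment itself carries heavy replicate noise (sigma = 1.5 on the
  enriched cells only, CV ≈ 2): reproducible baselines with
  irreproducible incubation responses. This is exactly the population
  the strict Dunnett criterion exists to reject — truly elevated in the
  mean (hence "doubled" and classified benthic) yet statistically
  unreliable at n = 3. A residual gray zone is irreducible: a feature
  whose mean is >= 2x Control but whose response is too noisy to test
  sometimes realizes a sample mean below 2x (misread as ambient) or an
  unluckily clean triplicate (misread as exometabolite); the planted
  recovery tests bound both leakages.
* **Planktonic exudates** are elevated only in the Day or Night Control
  incubations; **artifacts** in all incubations including both Controls.
  Planktonic features are deliberately not co-elevated in producer
  aquaria: under the artifact > benthic > planktonic precedence any
  producer-cell doubling would re-label them benthic, so the planted
  class encodes a Control-specific bloom.
* **Background** features appear in blanks at 0.7x their sample level
  (>= 1/2 makes the 2x-max-blank rule recover them with the 8-blank
  maximum); biological features appear in blanks at zero.
* **Formulas** come from five compound-class templates (lipid-like,
  sugar-like, peptide-like, P-rich, N-heterocycle) whose O:C / H:C /
  N:C / P:C marginals give lipids NOSC ≈ −1.5, sugars ≈ 0, and P-rich
  formulas at least one phosphorus. Each producer's exometabolites draw
  its signature template with probability 0.7 and shared
  primary-metabolite templates (sugar-like, peptide-like) otherwise —
  signature classes are producer-specific, common metabolites are not.
  Producer signatures: Dictyota lipid-like, Pocillopora P-rich, Porites
  peptide-like, CCA sugar-like, Turf N-heterocycle.
* **Subnetworks** chunk each producer's exometabolites (66% networked,
  ~8 nodes each); a share of ambient/planktonic features network
  separately. Annotations carry ZODIAC-style quality fields calibrated so
  roughly two thirds of formula-bearing features pass the quality filter.
* **Bulk chemistry**: DOC = baseline + slope x (summed exudate peak
  area) + Gaussian noise, the slope anchored so the Turf endpoint release
  is ~46 uM above Control and the noise scaled to realized day/night
  R^2 targets of 0.84 / 0.63; TDN and TDP derive from the per-sample
  exometabolite-weighted N:C and P:C plus inorganic pools with
  coral-leaning planted effects, so organic stoichiometry genuinely
  predicts the bulk nutrient pools; DO and pH carry photosynthesis /
  respiration signatures (algal daytime oxygenation, nighttime
  turf/coral drawdown).

One integer seed drives everything through named SeedSequence substreams
(classes, templates, baselines, noise, annotations, bulk, rt), so output
is bit-reproducible and regenerating one component does not perturb the
draws of another.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: chromatographic drift and retention-time
misalignment, isotope patterns and adduct redundancy, ionization
suppression that varies by matrix, correlated (compositional) noise
across co-eluting features, batch effects across a multi-study alignment,
and the long right tail of thousands of near-threshold real features. The
planted class structure is cleaner than reality; recovery rates here are
upper bounds on field performance, and the suite reads them as checks of
the pipeline's logic, not of instrument behaviour.

## Problem sizes and numerical choices

Default synthetic experiments carry ~1,070 features x 50 samples — large
enough for stable FDR behaviour and weighted summaries, small enough that
the full pipeline runs in seconds. Calibration checks use 200 replicate
null experiments of 1,000 features and a 10^6-draw Monte-Carlo oracle for
the Dunnett distribution. PERMANOVA defaults to 999 permutations.
Degenerate inputs follow explicit conventions: zero total variance in an
ANOVA gives p = 1 (flagged); zero residual variance with differing means
gives p = 0/1 by sign; constant features map to zero rows in z-score
transforms with a warning; all-zero samples are errors naming the sample.
Ties in consensus-class votes map to "unclassified".

## Known limitations

* Dunnett p-values assume the pooled-variance model; strongly
  heteroscedastic features (the planted benthic class is an extreme
  case) are tested conservatively at best.
* The congruency coefficient is asymmetric by design (label predicts
  category); swapping the arguments changes the value.
* Tier-scale reproduction of published dataset-level counts requires the
  deposited 258-sample feature table and is outside this package's test
  surface; the pipeline accepts such a table through the MZmine dialect
  reader unchanged.
* The sequential-SS PERMANOVA matches the adonis convention; marginal
  (Type III) tests are not implemented.
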