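# reefexo

Analysis of benthic primary-producer **exometabolomes** — the suites of
dissolved metabolites that corals and algae release into reef water —
from aligned untargeted LC-MS/MS feature tables.

Reef-building corals (*Porites*, *Pocillopora*), crustose coralline
algae, fleshy macroalgae (*Dictyota*), and turf algae all exude dissolved
organic matter, but the molecules differ: their identity, nutrient
content (N, P per carbon), and carbon oxidation state shape which
microbes can use them and how much energy they yield. `reefexo` takes a
feature x sample table of XIC MS1 peak areas from incubation experiments
(producer and Control aquaria, ambient starting water, process blanks)
plus formula/subnetwork annotations and bulk water chemistry, and
produces:

* a **five-stage feature classification**: background (blank-derived) →
  transient → ambient vs exudate (>= 2x over starting water) →
  statistically unambiguous **exometabolite features** (Dunnett vs
  Control, BH-FDR p < 0.05) → benthic / planktonic / artifact subtypes;
* **ordination** of samples on exometabolite relative abundances
  (arcsine-square-root + z-score, PCoA) with a sequential two-factor
  **PERMANOVA** (treatment, diel, interaction) and pairwise contrasts;
* **energetics**: per-sample carbon-weighted nominal oxidation state of
  carbon, NOSC = 4 − (−Z + 4a + b − 3c − 2d + 5e − 2f)/a for a formula
  C_a H_b N_c O_d P_e S_f with charge Z, and the Gibbs energy of carbon
  oxidation ΔG°cox = 60.3 − 28.5·NOSC kJ (mol C)⁻¹, with Tukey letter
  displays across producers;
* **stoichiometry**: abundance-weighted mean N:C, P:C, H:C, O:C per
  molecule, ternary P / N-no-P / CHO(S) class shares, and regressions of
  weighted N:C and P:C against bulk TDN and TDP;
* **subnetwork (molecular family) analyses**: summed relative abundance
  per family, Dunnett + FDR enrichment with a >= 2-fold conjunction
  rule, focus-network selection (abundant / diverse / enriched), and the
  congruency (Theil's U from a G² contingency analysis) of subnetwork
  and structural-class labels with treatment association;
* **bulk chemistry**: producer effects on DO, pH, DOC and nutrients
  (ANOVA + FDR + Dunnett), and the coupling of DOC to summed exudate
  ion abundance.

All statistics (ANOVA, Dunnett many-to-one via deterministic Gauss
quadrature of the shared-control multivariate t, Tukey HSD with compact
letters, BH FDR, PCoA, two-factor sequential PERMANOVA, OLS, G²
congruency) are implemented in `reefexo.stats` and cross-checked in the
test suite against independent implementations.

A first-class **synthetic experiment generator** (`reefexo.synthetic`)
emulates the full design — 42 incubation samples, 8 blanks, planted
feature classes with ~40-fold exometabolite enrichments, compound-class
formula templates per producer, DOC covarying with exudate signal — so
the entire pipeline is testable against known ground truth with no data
downloads. See `docs/methods.md` for the model and its limits.

## Worked example

Simulate one default experiment and run the full pipeline:

```bash
reefexo run-simulated --seed 1 --outdir out/
```

which prints the run manifest, including (seed 1):

```
"cascade_counts": { "background": 150, "transient": 106, "ambient": 316,
                    "exometabolite": 263, "benthic_exudate": 120,
                    "planktonic_exudate": 77, "incubation_artifact": 38 },
"permanova_r2":   { "treatment": 0.5876, "diel": 0.052,
                    "treatment:diel": 0.2866 },
"n_subnetworks": 38, "n_focus_subnetworks": 20
```

Reading: of 1,070 planted features the cascade removed 150 as
blank-derived background and 106 as unreplicated transients, kept 316 as
ambient reef-water DOM, and called 263 exometabolite features — the
statistically unambiguous producer exudates (250 were planted; realized
sensitivity 0.98, specificity 0.978). Producer identity explains ~59% of
compositional variance among samples, ten times the day/night share —
composition is organism-driven. The same library interface:

```python
from reefexo import SimulationConfig, generate_experiment, classify_features
sim = generate_experiment(SimulationConfig(seed=1))
result = classify_features(sim.feature_table, sim.metadata)
print(result.counts()["exometabolite"])   # 263
```

Per-producer energetics from the same run
(`out/sample_stoichiometry.tsv`, treatment means):

```
treatment     weighted_nosc   gibbs    nc      pc
Dictyota      -0.724          80.94    0.080   0.000    # lipid-rich: most reduced
Pocillopora   -0.288          68.51    0.153   0.027    # P-rich exudates
Porites       -0.185          65.56    0.226   0.000
Turf          -0.100          63.15    0.239   0.000
CCA           -0.003          60.40    0.081   0.000
```

The fleshy-algae exometabolomes are the most chemically reduced (lowest
NOSC, highest ΔG°cox — more catabolic energy per carbon), and the coral
*Pocillopora* releases the most phosphorus per carbon; both patterns are
planted by the generator's compound-class templates and recovered by the
pipeline.

Existing data go in through the same verbs with file inputs — including
MZmine-style wide quant tables:

```bash
reefexo run --features quant.csv --dialect mzmine --metadata samples.tsv \
        --annotations annotations.tsv --bulk chemistry.tsv --outdir out/
```

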