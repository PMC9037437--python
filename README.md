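# baripath

Analytics for linking long-term type-2-diabetes (T2D) outcomes after
Roux-en-Y gastric bypass (RYGB) to gut-microbiome composition and to
phenotypes transferred into mice by fecal-matter transplant (FMT).

Bariatric surgery resolves T2D in roughly half of patients, but the
binary remission definition hides how severe the persisting disease is.
`baripath` implements the full analysis chain a clinical-microbiome
study of this design needs:

* **Severity stratification** — patient-by-timepoint rows of seven
  clinical variables (HbA1C, fasting glucose, T2D duration, age, sex,
  glucose-lowering drug count, insulin use) are standardized, reduced by
  correlation-matrix PCA (Kaiser–Guttman retention, eigenvalue ≥ 1) and
  split into *Mild*/*Severe* clusters with Ward hierarchical clustering
  on the retained scores. Time-sensitive variables (age, T2D duration)
  keep their baseline values so severity cannot grow merely with time.
  The fitted model projects independent cohorts, labels trajectories
  (Stable-Mild, 5y-Rep+ good responders, 5y-Rep- poor responders),
  classifies ADA remission (HbA1C < 6.5 %, glucose < 7 mmol/L, no
  medication) and reports standardized odds ratios with perfect-
  separation handling.
* **Microbiome statistics** — seeded rarefaction without replacement
  (multivariate hypergeometric), 20 % prevalence and 0.1 % mean-abundance
  filters, alpha diversity, Bray–Curtis dissimilarity, PCoA (Gower
  double-centering, negative eigenvalues reported), capscale-style
  univariate dbRDA (Ezekiel-adjusted R², permutation p), Cliff's delta
  effect sizes with Cliff's asymptotic confidence intervals, Welch
  p-values with Benjamini–Hochberg adjustment, generalized-ESD (Rosner)
  outlier screening, Spearman clinical correlation grids.
* **Functional inference** — KO-group abundance as the sum of the
  abundances of carrier species (binary pangenome incidence), pathway
  collapse over a KEGG-style hierarchy, pathway-level group tests.
* **FMT analytics** — donor→recipient engraftment (shared detected
  species over donor species, both rarefied at the same depth and
  seed), geometric-mean collapse of the four animals per donor to avoid
  pseudoreplication, OGTT area under the curve (trapezoidal, baseline
  area subtracted), HOMA-IR, QUICKI, intestinal energy absorption, and
  donor-level two-group tests with Welch/Wilcoxon selection by
  normality and variance screens.
* **Synthetic study generator** — planted-truth cohorts, overdispersed
  count matrices, engraftment experiments and phenotype series with the
  statistical structure above, so the whole pipeline is testable
  without any sequencing download.

Key formulas, in the field's notation:

* Cliff's delta: δ = [#(a > b) − #(a < b)] / (n_a·n_b), positive when
  the Severe group is enriched.
* HOMA-IR = (fasting glucose (mg/dl) × 0.0555 × fasting insulin (mU/L)) / 22.5.
* QUICKI = 1 / (log₁₀ glucose (mg/dl) + log₁₀ insulin (mU/L)).
* Fold change between consecutive time points: (T_{x+1} − T_x) / T_x.

## Worked example

`examples/` holds one narrative script per capability. Running
`python examples/01_severity_clustering.py` fits the severity model on a
synthetic 100-patient cohort:

```
retained components (eigenvalue >= 1): 2
eigenvalues: [3.37 1.02 0.99 0.6  0.43 0.34 0.26]
baseline: 58% Severe
      1y: 29% Severe
      5y: 28% Severe

trajectories: {'Stable-Mild': 42, '5y-Rep+': 30, '5y-Rep-': 28}
remission at 5y: {'DR': 53, 'non-DR': 47}
```

The Severe share drops from 58 % to 28 % across the follow-up — the
planted post-surgery improvement — and the 30 good responders (5y-Rep+)
are patients who left the Severe cluster by year 5.

`python examples/02_differential_abundance.py` runs the microbiome side
(rarefy at 48,000 reads with seed 711 → prevalence and abundance
filters → Cliff's delta → BH):

```
165 taxa survive the prevalence and abundance filters

12 taxa at q < 0.1 (12/12 planted recovered):
        delta  ci_low  ci_high  p_welch       q
T0011  0.9433  0.8349   0.9813   0.0001  0.0021
T0004  0.8611  0.7002   0.9388   0.0001  0.0021
...
dbRDA: cluster explains 1.97% of genus-level community variation (p = 0.001)
```

All twelve planted Severe-enriched taxa are recovered with positive
deltas and no false positive; the dbRDA line is the share of
community-level variation the severity cluster explains.

The other scripts cover functional inference (`03`), the FMT experiment
with donor-level phenotype tests (`04`) and the fully orchestrated
pipelines with config hashing and byte-identical reruns (`05`). A thin
CLI wraps the same calls (`baripath fixtures|cluster|rarefy|diffab|
ordinate|dbrda|infer-ko|fmt|run-all`).

## Limitations

The package consumes taxon count tables; read-level processing
(basecalling, taxonomic binning) is out of scope, as are KEGG API
retrieval (membership tables are file inputs) and any wet-lab
protocol. Inferred KO/pathway abundances describe the community's gene
*potential*, not in-situ expression. See `docs/methods.md` for the
model assumptions, parameter defaults and numerical conventions.
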