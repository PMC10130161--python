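# spatialtme

Spatial immune profiling of multiplexed single-cell tissue data.

`spatialtme` is for researchers analyzing per-cell tables exported from
multiplexed immunofluorescence (mIF) image analysis of tumor tissue — one row
per segmented cell with coordinates in micrometres and boolean marker
positivity — who want to quantify *where* immune cells sit relative to
malignant cells, not just how many there are. It implements, as a tested and
reusable pipeline:

1. **Phenotyping** — marker co-expression rules (e.g. `CD3+CD8+` cytotoxic
   T-cells, `CD3+CD8negFOXP3+` regulatory T-cells) applied to cell tables
   from five staining panels; densities in cells/mm²; a cohort-median
   abundance filter (default ≥ 2 cells/mm²).
2. **Distribution patterns** — for each tissue core, the empirical
   cross-type nearest-neighbor G function from malignant (`CK+`) cells to an
   immune phenotype is compared with the theoretical curve of a Poisson
   process of the same intensity, `G(r) = 1 − exp(−λπr²)`. The **mixing
   score** is the normalized area between the curves,

   ```
   score = 100 · ∫[G_theo(r) − G_emp(r)] dr / ∫ G_theo(r) dr
   ```

   Scores in [−10, 10] classify the phenotype as **mixed** (interspersed
   among malignant cells); scores > 10 as **unmixed** (clustered apart).
3. **Distances** — per-subject median nearest-neighbor distances for 128
   (reference, target) phenotype pairs, dichotomized at the cohort median
   into **close** (≤ median) vs **long** (> median).
4. **Immunologic distribution groups** — crossing pattern × distance gives
   four groups (1: mixed/close, 2: mixed/long, 3: unmixed/close,
   4: unmixed/long), with group-wise density summaries (Kruskal–Wallis).
5. **Statistics** — rank tests against clinical variables, Kaplan–Meier /
   log-rank survival comparisons, and Cox proportional-hazards models
   (Efron ties) of spatial features adjusted for clinical covariates.

A synthetic-data module generates 1-mm TMA cores with known ground-truth
spatial regimes (complete spatial randomness, attraction to malignant cells,
segregated Thomas clusters) and cohorts with group-dependent survival, so
every stage is testable without access to patient data.

## Worked example

Simulate a 30-subject cohort and run the full pipeline:

```bash
spatialtme simulate --n-subjects 30 --seed 1 --out example_data
```

```python
import spatialtme as st

cfg = st.PipelineConfig(cell_table="example_data/cells.tsv",
                        clinical_table="example_data/clinical.tsv",
                        out_dir="example_results",
                        window_spec=("circle", 1000.0))  # known 1-mm cores
res = st.run_pipeline(cfg)
print(res["scores_by_phenotype"])
```

```
phenotype  median_score  n_subjects            pattern  median_score_ADC  median_score_SCC
     CD3+    -10.349224          30 mixed (attraction)          -22.2615         38.002786
```

The cohort-median CD3+ score is −10.3: T-cells are, on median, *more*
interspersed with malignant cells than a random arrangement would be
(negative = attraction; the cohort mixes subjects simulated in all four
groups, so ADC/SCC medians differ by chance). Per-subject rows in
`res["distances_by_subject"]` carry the close/long dichotomy:

```
subject_id   reference target  median_nn_um distance_class
     S0000         CK+   CD3+     47.484694          close
     S0001         CK+   CD3+    153.390558           long
```

and `res["survival_cox"]` reports the Cox model of overall survival on group
membership (group 1 = reference) adjusted for histology, smoking and
mutation status, with columns `B, SE, Wald, HR, CI_lower, CI_upper, p`.

All tables are also written as TSV under `example_results/`, together with a
`manifest.json` sufficient to reproduce the run.

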