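# Methods

This note documents the statistical model behind `spatialtme`, the
estimators and their numerical choices, what the synthetic-data generator
does and does not emulate, and the design decisions taken where the
methodology was genuinely open.

## Data model

The unit of observation is a tissue-microarray (TMA) core: a ~1-mm-diameter
circular tissue sample imaged with one of five multiplexed
immunofluorescence panels. Image analysis yields one row per segmented cell
with x/y coordinates (µm) and boolean positivity for each of the panel's
markers. Phenotypes are defined by co-expression rules (all
required-positive markers positive, all required-negative markers negative);
rules are nested, so a `CD3+CD8+` cell also counts as `CD3+`. Malignant
cells are the cytokeratin-positive (`CK+`) population. Densities are
cells/mm² within the core's observation window; phenotypes whose cohort
median density falls below 2 cells/mm² are excluded from spatial scoring, as
sparse patterns do not support stable distribution estimates.

## Cross-G mixing score

For reference points (malignant cells) and target points (an immune
phenotype) in a shared window, the empirical cross-G function is the CDF of
the reference-to-nearest-target distance. Under complete spatial randomness
(CSR) with target intensity λ the theoretical curve is
`G(r) = 1 − exp(−λπr²)`; λ is estimated as the realized target count over
the window area, so the comparison asks only *where* the targets are, not
how many there are.

The mixing score is the area between the curves, normalized to the area
under the theoretical curve and expressed in percent:

    score = 100 · ∫₀^rmax [G_theo − G_emp] dr / ∫₀^rmax G_theo dr

* `score ≈ 0` — targets are arranged as CSR predicts ("mixed").
* `score > 0` — the empirical curve lags the theoretical one: targets are
  farther from typical malignant cells than CSR predicts (segregation /
  clustering). Scores > 10 are classified "unmixed".
* `score < 0` — targets are closer than CSR predicts (attraction). The
  mixed band is [−10, 10]; scores below −10 are still reported as mixed but
  flagged "(attraction)", since only the mixed/unmixed dichotomy is defined
  and strong attraction is an interspersed arrangement.

A ±10 band corresponds to a 10% area deviation from the CSR curve.

Numerical choices:

* **r grid** — 0 to `r_max` in 1-µm steps; `r_max` defaults to the radius
  where `G_theo` reaches 0.99, capped at 200 µm (≈ a core radius), so the
  flat tail of both CDFs does not dilute the score. Trapezoidal integration.
* **Edge correction** — border (reduced-sample) correction by default: at
  each r only reference points at least r from the window boundary enter
  numerator and denominator, removing the bias from neighbors censored
  outside the window. The reduced-sample estimator is not automatically
  monotone (its denominator changes with r), so a running maximum enforces
  the CDF shape; radii at which no reference point survives are NA and
  truncate the score integral (logged). `edge_correction="none"` gives the
  raw empirical CDF.
* **Minimum counts** — cores with fewer than 5 reference or 5 target cells
  yield an NA score: an empirical CDF on fewer points is dominated by noise.
  The abundance filter above operates at the phenotype level; this guard
  operates per core.
* **Windows** — the default observation window for real data is the convex
  hull of *all* cells in the core (robust to partially filled cores, and
  shared between reference and target so both use one area). A fitted
  circle of known diameter or an explicit window can be configured; for
  simulated data the generator's exact 1-mm circle should be used, because a
  hull around a sparse phenotype under-covers the window and inflates the
  intensity estimate.
* **Aggregation** — scores are computed per core and aggregated per subject
  by median (triplicate cores), then summarized per phenotype as cohort
  medians, optionally split by histology. How the original triplicates were
  pooled is not documented anywhere we know of; the median is robust to a
  single failed core.

## Distance metrics and dichotomization

For each (reference, target) phenotype pair the per-core median of
reference-to-nearest-target distances is computed without edge correction (a
median of distances, not a CDF estimate, and medians are hardly affected by
boundary censoring at core scale), aggregated per subject by median. The
shipped default panel has 128 pairs: malignant cells to 26 canonical immune
phenotypes, plus six special references (checkpoint-positive/negative
malignant cells and regulatory T-cells) each measured to 17 T/B-cell
phenotypes.

Per pair, subjects are dichotomized at the cohort median: values ≤ median
are "close", values > median "long", so ties go to close and close never
outnumbers long by construction. The dichotomy is rank-based and therefore
invariant to monotone transforms of the distances. It can optionally be
computed within histology subgroups.

## The four immunologic distribution groups

Crossing the pattern of an anchor phenotype (default `CD3+`, typically the
predominant immune population) with its distance class gives:

| group | pattern | distance |
|-------|---------|----------|
| 1 | mixed | close |
| 2 | mixed | long |
| 3 | unmixed | close |
| 4 | unmixed | long |

NA in either input yields no assignment. Group-wise phenotype-density tables
use the Kruskal–Wallis test across groups (groups with < 2 subjects are
reported but excluded from the test; an all-ties configuration is reported
as statistic 0, p 1 — the degenerate null).

## Survival statistics

Associations of continuous spatial features with clinical variables use the
Wilcoxon rank-sum test (two levels) or Kruskal–Wallis (more). Survival
comparisons use Kaplan–Meier estimates with the two-sided log-rank test, and
Cox proportional-hazards models with Efron handling of tied event times
(`lifelines`), reporting B, SE, the Wald statistic (B/SE)², HR = exp(B) and
the 95% CI. P-values are unadjusted, mirroring common practice for these
exploratory panels; a Benjamini–Hochberg helper is provided. Constant
covariates are rejected, near-perfectly collinear ones dropped with a
warning, and suspected complete separation (|B| or SE > 10) is flagged but
not "repaired" — such fits occur in practice when a feature level has no
events and the user should see them.

## Synthetic-data generator

`simulate_core` draws malignant cells as a homogeneous Poisson process in
the core window and immune phenotypes in one of three regimes:

* **csr** — homogeneous Poisson at the requested intensity;
* **attraction** — each immune cell is a uniformly chosen malignant parent
  plus an isotropic Gaussian offset (sd = `attraction_scale`), emulating
  infiltration between tumor cells;
* **segregated_cluster** — a Thomas process (Poisson parents, Poisson
  offspring with Gaussian spread) whose parents keep a minimum exclusion
  distance from every malignant cell, emulating immune aggregates
  segregated from tumor nests. Thomas was chosen as the standard tractable
  clustered point process; nothing in the pipeline depends on this choice.

Points falling outside the window are redrawn up to a retry cap, keeping
realized intensities near nominal; an infeasible exclusion radius raises an
error naming the phenotype. Coordinates are continuous µm, no pixel
snapping; fixed seeds give bit-identical output.

`simulate_cohort` assigns each subject a ground-truth group and simulates
its cores with presets that realize the group for the anchor phenotype
(malignant intensity 40 cells/mm², low enough for exclusion-radius sampling
to remain feasible):

| group | regime | parameters | target intensity | realized median distance |
|---|---|---|---|---|
| 1 | attraction | scale 12 µm | 100/mm² | ~10 µm |
| 2 | attraction | scale 150 µm | 12/mm² | ~132 µm |
| 3 | segregated | κ=120/mm², µ=2, scale 10, excl. 20 µm | 240/mm² | ~49 µm |
| 4 | segregated | κ=15/mm², µ=8, scale 20, excl. 80 µm | 120/mm² | ~134 µm |

These presets were calibrated once, before the validation tolerances were
frozen. Two aspects matter: groups 1/3 sit clearly below and groups 2/4
clearly above the cohort median distance, and the two "long" groups have
*matched* distance distributions. The latter is deliberate: the
cohort-median dichotomy always labels exactly half the cohort close, so
whenever the true close mass is below one half the excess must come from the
long groups — matching their distributions makes that structural crossing
split between them in proportion to their prevalence instead of draining a
single group. With group probabilities (0.25, 0.30, 0.10, 0.35) about 0.15
of the cohort crosses, ~0.07–0.09 per long group; end-to-end recovery is
therefore validated against the realized ground-truth frequencies at a
±0.10 tolerance. Survival times are exponential with hazard
`baseline_hazard · exp(log_hazard_by_group[g])`, censoring exponential,
binary clinical covariates Bernoulli.

What the generator does **not** emulate: marker-intensity values (only
boolean positivity), inhomogeneous cell fields and tissue architecture
(tumor/stroma compartments, vessels, necrosis), segmentation errors,
panel-to-panel registration, or correlations between spatial structure and
clinical covariates. Passing the simulation-based tests shows the
estimators and the pipeline recover known structure under these idealized
conditions; it does not certify performance on real tissue, where window
misspecification and inhomogeneity are the dominant hazards.

## Validation problem sizes

The simulation-based checks use 200 cores for CSR calibration and
segregation sensitivity, 1000 replicates for log-rank type-I error, 100
cohorts of n=500 for Cox recovery, and one 400-subject cohort (three cores
each) for end-to-end recovery; `scripts/acceptance.py` re-runs the same
analyses at 500 log-rank replicates, 50 Cox cohorts and 300 subjects. These
sizes give Monte-Carlo standard errors comfortably inside the stated
tolerances.

## Known limitations

* The mixing score compares against a *homogeneous* Poisson reference; in
  strongly inhomogeneous tissue a phenotype can score "unmixed" merely
  because the tissue itself is patchy.
* Border correction assumes the window is the true sampling region; a hull
  window around sparse cores under-covers it.
* The close/long dichotomy discards effect size and forces a 50/50 split by
  construction (see above).
* Cox models are fit without proportionality diagnostics beyond the
  separation/collinearity warnings; K-, L- and pair-correlation functions,
  CSR envelope tests and inhomogeneous G are out of scope.
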