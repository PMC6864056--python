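# histodensity

Mammographic breast density — the proportion of the breast occupied by
fibroglandular (non-fatty) tissue — is one of the strongest breast-cancer
risk factors, yet its histologic basis is incompletely understood. Given
whole-slide tissue-class maps of breast biopsies (per-pixel labels for
epithelium, stroma and fat, as produced by an upstream segmentation model),
this package asks two questions:

1. **Which histologic features track percent fibroglandular volume (FGV)?**
2. **Do those features distinguish invasive cancer from benign disease,
   separately among women with high and low density?**

It is aimed at computational-pathology and cancer-epidemiology researchers
who have label maps and patient-level density/diagnosis tables and want a
tested, reproducible version of this analysis — plus a synthetic cohort
generator so every stage can be validated without access to clinical data.

## The method

For each slide a 37-feature vector is computed in three families:

* **Global tissue quantities** — area of fat, stroma and epithelium in µm²,
  and each normalised to total tissue area (%).
* **Epithelial morphology** — number of connected epithelial regions
  `A_1, …, A_n`, with {mean, median, SD, IQR, max} summaries of region area
  and eccentricity.
* **Spatial arrangement** — the *area-Voronoi diagram* assigns every tissue
  pixel to the nearest region: `V_a(A_i)` is the set of pixels whose
  distance to `A_i` is ≤ the distance to every other region. Features
  summarise influence-zone areas, the fill ratio `|A_i| / |V_a(A_i)|`
  (→ 1 for coalescent growth, → 0 for sparse epithelium), the ratio of
  region area to the non-epithelial part of its zone, and each region's
  number of Delaunay-triangulation neighbours.

Per-patient vectors (median across slides) feed a random-forest regression
of global and localized FGV with Gini-importance ranking, evaluated as the
Spearman correlation *r* between predicted and actual FGV on a held-out 31%
test split. A random-forest classifier then predicts invasive vs benign
diagnosis (in-situ excluded) within high/low FGV strata defined by the
training-population median, evaluated by ROC AUC with class-stratified
percentile-bootstrap 95% CIs; AUCs of independent strata are compared with
a bootstrap difference test.

The synthetic generator ties FGV to tissue composition by construction
(`FGV = 100 × (1 − fat fraction of tissue)` + noise) and makes invasive
patients differ from benign ones *only* in epithelial organisation
(densely packed, partially merged regions vs dispersed hard-core placement)
at matched epithelial fraction — so recovering "stroma and fat predict FGV"
and "organisation, not quantity, predicts cancer" are falsifiable tests.

## Worked example

```python
import histodensity as hd

cfg = hd.SimulationConfig(n_patients=80, slides_per_patient=2, rng_seed=7)
table, maps = hd.generate_cohort(cfg)
slides, patients = hd.extract_cohort_features(table, maps)

model, ranking = hd.train_fgv_regressor(patients, "global_fgv", seed=7)
r = hd.predict_and_correlate(model, patients, "global_fgv")
print(f"held-out Spearman r (global FGV): {r:.3f}")
print(ranking.head(3).to_string(index=False))

cutpoint, strata = hd.stratify_by_median(patients, "global_fgv")
fit = hd.train_cancer_classifier(patients[strata == "high"], seed=7)
report = hd.bootstrap_auc_ci(fit["scores"]["score"], fit["scores"]["truth"],
                             n_bootstrap=2000, seed=7)
print(f"high-FGV stratum (cutpoint {cutpoint:.1f}%): "
      f"AUC {report.auc:.2f} (95% CI {report.ci_low:.2f}-{report.ci_high:.2f})")
```

Output:

```
held-out Spearman r (global FGV): 0.966
           feature  importance  rank
stroma_amount_norm    0.189087     1
   fat_amount_norm    0.178032     2
     stroma_amount    0.132651     3
high-FGV stratum (cutpoint 54.6%): AUC 1.00 (95% CI 1.00-1.00)
```

The normalised stroma and fat quantities rank 1–2 for FGV — the
relationship the generator builds in — and the high-density stratum
classifier separates invasive from benign patients on spatial-arrangement
features. (At this toy size, 80 patients, separation is complete; the
default 580-patient conditions give AUCs near 0.98.)

A command-line interface mirrors the library:

```bash
histodensity run-all --out runs/demo --seed 11
histodensity simulate --out cohort/ --seed 3
histodensity extract --cohort cohort/cohort.csv --mpp 0.5 --out features/
```

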