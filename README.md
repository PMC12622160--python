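# radharm

Harmonization and training-set augmentation for radiomics-based lung-cancer
early detection.

## The problem

Screening CT catches lung nodules long before a radiologist will call them
suspicious, but radiomics classifiers trained only on such
*early-development* nodules face two walls: malignancy is rare in that
population, and radiomic features inherit strong dependence on acquisition
protocol (contrast enhancement, KVP, focal spot, manufacturer).  Training
can be augmented with *later-development* nodules whose diagnoses were
confirmed — at the price of a subtle trap: contrast is given
preferentially to worrying lesions and accumulates more in tumors, so in
augmented data the CE protocol is confounded with malignancy *and* its
effect size differs between benign and malignant tissue.  Harmonizing such
data "collectively", as if one correction fit all biologies, can destroy
the very signal augmentation was meant to add.

`radharm` implements the full experimental machinery for studying this:

* **`radharm.combat`** — parametric empirical-Bayes ComBat (location–scale
  batch correction with optional categorical covariates), bit-compatible
  with the reference implementation and applicable to unseen scans using
  training statistics only;
* **`radharm.opncb`** — Optimized Permutation Nested ComBat: sequential
  harmonization over several acquisition parameters with the order chosen
  by exhaustive permutation search, in three modes — *collective* (no
  biological distinction), *covariate* (dataset label as covariate), and
  *separate* (one estimator chain per dataset) — plus the scan-exclusion
  rules (min-3 per protocol, unseen-protocol test exclusion);
* **`radharm.screen`** — the Kruskal–Wallis acquisition-dependence screen
  (run separately on benign and malignant augmentation data; a feature is
  dependent if p ≤ 0.05 in either) and its uniform-group null validation;
* **`radharm.pipeline`** — grouped stratified 5×10-fold cross-validation,
  cumulative training-set augmentation, LASSO (α = 0.05) feature
  selection, linear SVM (C = 1) classification, learning curves with
  logarithmic fits, and DeLong / Wilcoxon / Holm–Bonferroni method
  comparisons;
* **`radharm.simulate`** — a synthetic cohort generator encoding the
  patient → nodule → scan hierarchy, dataset-specific protocol
  frequencies, biology-dependent batch effects, and an attenuated
  early-development class signal, with an exact ground-truth ledger.

## Worked example

Generate a cohort under the default study conditions and inspect it:

```python
from radharm import default_config, generate_cohort, summarize_cohort
cohort, truth = generate_cohort(default_config(), seed=101)
print(summarize_cohort(cohort).round(1))
```

```
               patients  patients_pct_cancer  nodules  nodules_pct_cancer  scans  scans_pct_cancer
EARLY                58                 25.9       82                19.5    187              16.6
AUG_BENIGN           21                  0.0       28                 0.0     36               0.0
AUG_MALIGNANT        58                100.0       59               100.0    189             100.0
Total               117                 49.6      148                39.9    412              53.4
```

187 early-development scans at 16.6% malignant pool with 225 confirmed
augmentation scans to 53.4% malignant over 412 scans — augmentation
removes the class imbalance.  Now run one trial of the pipeline under each
harmonization mode:

```python
from radharm import (PipelineConfig, make_splits, augment_training,
                     run_trial, CohortTable)
import pandas as pd

early = cohort.select_dataset("EARLY")
aug = cohort.subset((cohort.df.dataset_label != "EARLY").to_numpy())
cfg = PipelineConfig(n_repeats=1, fractions=(1.0,), seed=101)
full = CohortTable(pd.concat([early.df, aug.df], ignore_index=True),
                   list(early.feature_names))
sp = make_splits(early, aug, cfg)[0]
train = full.subset(augment_training(sp, 1.0))
test = full.subset(sp.test_scan_ids)
for mode in ("collective", "covariate", "separate"):
    r = run_trial(train, test, mode, cfg, trial_id=sp.trial_id)
    print(f"{mode:11s} independent={r.independent_fraction:.2f} "
          f"selected={r.n_selected:2d} test AUC={r.metrics['roc_auc']:.2f}")
```

```
collective  independent=0.23 selected= 7 test AUC=0.68
covariate   independent=0.36 selected= 9 test AUC=0.61
separate    independent=0.99 selected=20 test AUC=0.84
```

The independence column is the fraction of the 107 features the
Kruskal-Wallis screen passes after harmonization: collective harmonization
leaves barely a quarter of the features usable, separate harmonization
nearly all of them.  A single trial's AUC is noisy (here collective
happens to beat covariate on 40 test scans); over the full 50-trial
experiment at full augmentation (`scripts/acceptance.py --seed 1`) the
means separate cleanly —

| mode       | % independent features | mean test ROC-AUC |
|------------|-----------------------:|------------------:|
| collective |                   27.6 |             0.556 |
| covariate  |                   40.1 |             0.661 |
| separate   |                   97.2 |             0.808 |

— the headline finding: harmonization that ignores the biological
distinctness of the augmentation datasets strips acquisition-independent
features and with them the malignancy signal, while covariate and
separate harmonization preserve both.

A shell interface wraps the same steps (`radharm generate`, `radharm
harmonize`, `radharm screen`, `radharm run-experiment`); see
`radharm --help`.

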