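# fmripredict

Comparing and scaling resting-state fMRI feature subtypes for
brain-behavior prediction.

Predicting behavioral variables (cognition, age, sex, mental health, ...)
from resting-state fMRI is a central step toward neuroimaging biomarkers.
A key design choice is *which feature* to extract from the BOLD signal.
This package implements a reusable, fully tested version of a nine-way
feature comparison framework for parcellated resting-state data:

| family | features | dimension |
|---|---|---|
| functional connectivity | `fc` | R(R−1)/2 |
| region-wise statistics | `mean`, `sd`, `mssd` (BOLD variability), `falff` | R |
| graph signal processing | `psd`, `sdi`, `coupled_fc`, `decoupled_fc` | R or R(R−1)/2 |

with R = 274 regions in the default parcellation (so FC-family features
have 37 401 edge entries).

The GSP features live on **connectome harmonics**: the eigenvectors U of
the symmetric normalized Laplacian L = I − D^{−1/2} A D^{−1/2} of a
*consensus* structural connectome A built from the training subjects only
(occurrence-ranked binary mask ⊙ mean weights). The graph Fourier
transform x̂ = UᵀX expresses each BOLD frame in harmonics; a cutoff at
⌊R/2⌋ splits the signal into a structure-**coupled** (low-harmonic) and
**decoupled** (high-harmonic) part. From these we compute the graph power
spectral density PSD_k = ‖x̂_k(·)‖₂, the structural decoupling index
SDI_r = ‖x_high,r‖₂ / ‖x_low,r‖₂, and FC of the filtered signals.

Evaluation is family-aware nested cross-validation: 10 random
train/test partitions that never split a family (test ≈ 15 % of the
cohort), 3 inner folds for hyperparameter selection (elastic net, linear
kernel ridge, elastic-net classifier, linear SVM), standardization fit on
training data only, scored with R² (continuous targets) or accuracy
(sex). Significance uses a permutation null: targets reshuffled 100
times per split (1000 null scores); a feature predicts above chance iff
its mean real score exceeds the null's 95th percentile. A scaling module
repeats the pipeline over training-set fractions (0.2–1.0) and scan-time
amounts (0.25–4 sessions; 3.6–57.6 min).

Because the original cohort data are access-restricted, the package ships
a synthetic cohort generator with known ground truth (community-structured
SCs, BOLD with graph-spectral energy concentrated on low harmonics,
targets that are noisy linear functions of designated features, families
of size 1–5, motion confounds), so every stage is testable end to end.

## Worked example

```python
import numpy as np
from fmripredict import (BehaviorPrediction, CohortConfig, ModelSpec,
                         build_feature_matrix, generate_cohort)

cfg = CohortConfig(n_subjects=120, n_regions=16, n_sessions=2,
                   frames_per_session=100, n_communities=4, seed=42)
cfg.effect_size_per_target = {**cfg.effect_size_per_target, "cognition": 0.5}
cohort = generate_cohort(cfg)                 # 50% of cognition variance on FC edges

edges = build_feature_matrix(cohort, "fc")    # 120 subjects x 120 FC edges
y = np.array([r.targets_continuous["cognition"] for r in cohort])
model = BehaviorPrediction(edges.values, y, [r.family_id for r in cohort],
                           model=ModelSpec("krr", grid={"alpha": [0.1, 1.0, 10.0]}),
                           seed=0, feature_name="fc", target_name="cognition")
res = model.fit(n_permutations=50)
print(res.summary())
```

prints

```
Behavior prediction results
===========================
target:  cognition
feature: fc (dim 120)
model:   krr   metric: R^2
splits:  10 (test fraction 0.15, 3 inner folds)

   target feature model  mean    sd  median    q1    q3  p_value
cognition      fc   krr 0.123 0.216   0.203 0.030 0.235    0.014
null: 500 permuted scores, 95th percentile -0.023 -> significant
```

The mean test R² of 0.123 over the 10 family-respecting splits (median
0.203 — small test sets make individual splits noisy) exceeds the 95th
percentile of the 500-score permutation null, so FC predicts the planted
cognition signal above chance (p ≈ 0.014 by the +1-smoothed null rank).

The same comparison runs from the shell:

```bash
fmripredict synth   --config run.yaml --out cohort/
fmripredict run-all --config run.yaml        # tables, per-split scores, plots
```

where `run.yaml` lists the cohort directory, features, targets, models,
split scheme, permutation count and optional scaling grid (see
`fmripredict.config.RunConfig`; unknown keys are rejected).

## Layout

- `fmripredict.synthetic` — cohort generator and factor-subset partition
- `fmripredict.preprocess` — frame discard, confound regression, high-pass
- `fmripredict.connectome` — consensus SC and harmonic basis
- `fmripredict.features` — the nine feature subtypes
- `fmripredict.prediction` — splits, nested CV, permutation test,
  `BehaviorPrediction` / `BehaviorPredictionResults`
- `fmripredict.scaling` — sample-size × scan-time grid
- `fmripredict.pipeline`, `config`, `cli`, `plots` — orchestration, YAML
  config, command line, figures

See `docs/methods.md` for modeling assumptions, parameter choices, and
known limitations.
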