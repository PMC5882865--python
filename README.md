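# dtsvm — identifying migratory insect species from radar-observable features

Entomological radar can monitor nocturnal insect migration without disturbing
it, but telling *which* species is flying overhead has remained out of reach.
Zenith-pointing radars retrieve three physical features per target from its
radar cross-section and echo modulation: body **mass** (mg, ±40% at current
precision), **wingbeat frequency** (Hz, ±1 Hz) and the body
**length-to-width ratio** (a shape descriptor). **Body length** (mm) is not
yet radar-retrievable but is a plausible future observable.

`dtsvm` implements a decision-tree support vector machine (DTSVM) that
identifies 23 migratory insect species (moths, hawk-moths, pyralids, a
dragonfly and a damselfly trapped in the Bohai Gulf migration corridor) from
these features, and quantifies how identification accuracy depends on radar
measurement precision. It is aimed at radar entomologists and quantitative
ecologists who want to reproduce, stress-test or extend feature-based species
identification.

## Method

An N-class problem is decomposed into N−1 binary ones arranged in a binary
tree. The topology is driven by the **inter-class separability factor**
between class groups *i* and *j*:

    dm_ij = d(m_i, m_j) / (σ_i + σ_j)

where `d(m_i, m_j)` is the Euclidean distance between the class centers on
standardized features and `σ_i² = tr Σ_i` is the total within-class scatter.
The least-separable pair of groups is merged repeatedly (recomputing pooled
statistics) until one group remains; read top-down, the resulting tree makes
its most separable split at the root, so easy decisions are made before hard
ones and errors cannot cascade through them. Each internal node is a
two-class RBF SVM trained on the standardized samples of its species set; a
test sample cascades root→leaf and the leaf is the predicted species.

Because raw per-specimen data are not published, cohorts are regenerated
from the per-species summary statistics bundled with the package (mean,
standard deviation and observed range of the four features for all 23
species): each species is extended to 5,000 Gaussian samples, split 50/50
into training and testing halves. Radar imprecision is emulated by injecting
additive wingbeat noise (σ in Hz) and multiplicative relative errors
(calibrated so the realised root-mean-square percent error, RMSPE, equals
the stated level) into both halves before rebuilding and retraining.

## Worked example

```python
from dtsvm import ExperimentConfig, run_noise_free

reports = run_noise_free(ExperimentConfig(samples_per_class=1000, seed=1))
for key, report in reports.items():
    print(key, round(report.mean_accuracy, 2))
```

prints

```
three_feature 0.96
four_feature 0.97
```

— the mean per-species identification accuracy (recall averaged over the 23
species) on the held-out half, using the three radar-retrievable features
and with body length added. Under the four built-in measurement-error
scenarios (`run_error_cases`; wingbeat σ = 1 Hz throughout, mass and shape
RMSPE 40 → 20 → 10%, body length 10% in the last):

```
Case I    0.54      Case II   0.69      Case III  0.83      Case IV   0.87
```

so identification at current radar precision (Case I) is poor, improves
steeply as mass/shape retrieval sharpens, and species with distinctive
wingbeat bands (the hummingbird hawk-moth at 182–289 Hz, the globe-skimmer
dragonfly at 120–155 Hz) stay at 1.00 accuracy in every scenario.

The same pipeline is scriptable from the shell:

```sh
dtsvm generate --n-per-class 5000 --features mass,wbf,lwr --seed 1 --out cohort.csv
dtsvm build-tree --train train.csv --newick-out tree.nwk
dtsvm train --train train.csv --model-out model.joblib
dtsvm evaluate --model model.joblib --data test.csv
dtsvm noise-free --seed 1    # noise-free accuracies, 3 and 4 features
dtsvm error-cases --seed 1   # error cases I-IV
```

See `examples/` for short narrative scripts covering cohort generation,
separability analysis, noise-free identification and error robustness, and
`docs/methods.md` for modelling assumptions and parameter choices.

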