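# gaitrisk

Do the *extremes* of daily-life gait quality tell us more about fall risk in
older adults than typical gait? `gaitrisk` is a Python package for answering
that kind of question with week-long trunk accelerometry: it extracts gait
characteristics from 10-second walking epochs, summarizes each person's week
into 10th/50th/90th percentile values, builds nested stepwise logistic
fall-prediction models, and tests whether adding sensor-derived parameters —
or replacing medians by extremes — significantly improves discrimination.

It is aimed at researchers in wearable gait analysis and fall-risk
epidemiology who want a tested, reproducible implementation of this analysis
chain, together with synthetic-data generators whose ground truth is known,
so every stage can be validated before it ever touches real data.

## What it computes

**Per-epoch gait characteristics** (30 in total) from tri-axial trunk
acceleration (VT/ML/AP axes, 100 Hz, dynamic acceleration): gait speed and
per-step speed variability via the inverted-pendulum model
(step length = 2√(2ℓh − h²) from the vertical excursion *h* and leg length
ℓ); stride frequency/time; and per axis: RMS, stride regularity (unbiased
autocorrelation at the stride lag), frequency variability, low-frequency
power percentage, index of harmonicity, harmonic ratio (even/odd stride
harmonic amplitudes; odd/even on ML), local dynamic stability (Rosenstein
short-term log-divergence rate), sample entropy (m = 5, r = 0.3 · SD), and
dominant-frequency amplitude.

**Week summaries.** Epochs suspected to reflect running (stride time
< 0.8 s or VT RMS > 5 m/s²) are discarded; each characteristic is reduced
to its 10th/50th/90th percentiles per participant — percentiles rather than
raw min/max because raw extremes are unreliable between weeks (the package
ships ICC(2,1) screening to demonstrate exactly that).

**Risk models.** Univariate logistic scans on z-transformed predictors; then
three stepwise forward logistic models (entry: lowest Wald p < .05,
admissible only if |Spearman ρ| ≤ .7 with already-selected parameters):

* Model 1 — questionnaire only (fall history, GDS depression score),
* Model 2 — + physical-activity amounts + characteristic medians,
* Model 3 — medians replaced by the 10th/90th percentile wherever the
  extreme has the stronger univariate association.

Discrimination is the in-sample AUC, calibration the Hosmer–Lemeshow test.

**Model comparison.** A Monte Carlo block-permutation test: all
sensor-derived columns of a participant are reassigned *jointly* to another
random participant (outcome and questionnaire stay put, within-block
correlations are preserved), both models are rebuilt from scratch on each of
1000 permuted datasets, and the p-value is the fraction of permutations
whose AUC increase beats the observed one.

**Synthetic cohorts.** Two generators with exact ground truth: a
signal-level generator (stride-harmonic acceleration model with controllable
noise, frequency wander, asymmetry and vertical excursion) and a
feature-level generator (hierarchical epoch-level feature draws with
participant-specific dispersion, percentile summaries, logistic outcome on
the realized columns) for model-level studies at scale.

## Worked example

```python
import gaitrisk as gr

params = gr.FeatureCohortParams(
    n_participants=202, epochs_per_participant=50, seed=1,
    outcome_coefficients={
        "fall_history": 0.5, "gds": 0.35, "lying_duration": -0.35,
        "sample_entropy_vt__p10": 0.65,
        "low_frequency_percentage_vt__p50": 0.40,
    },
)
cohort, truth = gr.synth_feature_cohort(params)
models = gr.build_models(cohort)
for k, m in models.items():
    print(k, round(m.auc, 3), m.parameters)
cmp12 = gr.compare_models(cohort, "model1", "model2",
                          gr.PermutationSpec(n_permutations=1000, seed=2))
print("p(model1 -> model2) =", cmp12.p)
```

prints (seed 1):

```
1 0.604 ['fall_history']
2 0.755 ['sample_entropy_vt__p50', 'n_transitions', 'fall_history',
         'lying_duration', 'low_frequency_percentage_vt__p50']
3 0.752 ['sample_entropy_vt__p10', 'n_transitions',
         'dominant_frequency_amplitude_vt__p90', 'fall_history']
p(model1 -> model2) = 0.02
```

Reading: the questionnaire-only model discriminates weakly (AUC 0.60);
adding activity amounts and gait-characteristic medians raises the AUC to
0.75, and the permutation test says an improvement this large arises in only
2% of datasets in which the sensor block was decoupled from the outcome —
the sensor data genuinely help. Replacing medians with stronger-associated
extremes (Model 3) changes the AUC only marginally here, mirroring the
typical finding that extremes add little over medians in prediction even
when their univariate associations are stronger.

There is also a CLI over the same functions:

```bash
gaitrisk simulate  --config cohort.yaml --out data/ --seed 1
gaitrisk extract   --in data/epochs.csv --out features.csv
gaitrisk summarize --in features.csv --out summary.csv
gaitrisk fit       --summary summary.csv --cohort data/cohort.csv --out models/
gaitrisk compare   --summary summary.csv --cohort data/cohort.csv \
                   --a model1 --b model2 --nperm 1000 --seed 1 --out cmp.json
gaitrisk run-all   --out study/ --seed 1
```

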