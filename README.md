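# chronogauge

Ensemble estimation of circadian time (CT) from a single bulk
transcriptome sample.

Plant circadian biology usually requires dense time-course experiments:
to know where a plant's internal clock is pointing, you sample every
couple of hours around the cycle. `chronogauge` goes the other way — it
learns, from labelled multi-experiment time courses, a bagging-like
ensemble of small neural networks that can read the internal time off
the expression of a handful of rhythmic marker genes in *one*
time-pointed RNA-seq (or microarray) sample. Comparing estimated CT with
the known sampling time then turns single snapshots into hypotheses
about clock dysfunction: a mutant whose estimates run ahead of the clock
looks short-period, one that lags looks long-period, and the spread of
estimates across ensemble members (the "circadian fingerprint") hints at
which pathways drifted.

## The method

Time of day lives on a 1440-minute circle, so the regression target is
the unit-circle encoding

    s = sin(2π·t/24 + π/2),   c = −cos(2π·t/24 + π/2)   (t in hours)

and each sub-predictor is a 3-hidden-layer perceptron with two linear
output nodes trained with the angular loss

    Θ = mean(1 − cos_sim((s, c)_true, (s, c)_pred)),

which is scale-invariant in the prediction and respects the midnight
wrap-around. Decoding is `t = atan2(s, −c)` mapped back to [0, 24) h.

Each of the (by default 100) ensemble members gets its own gene feature
set from a phase-balanced sequential feature selection (SFS): bootstrap
50 % of the circadian-significant genes (rhythmicity prior, Q < 0.05),
shortlist the 25 most significant per 4-hour peak-phase bin, then
alternate forward insertions into under-represented phase bins and
reverse eliminations, scoring every move by fivefold cross-validated
mean absolute circular error, and keep the best state visited. Learning
rate, batch size and L2 factor are tuned per member by random search;
test-time estimates are aggregated with a circular mean. Baselines
implemented for head-to-head comparison: the classical molecular
timetable method (cosine fits over time-indicating genes, r ≥ 0.89) and
a partial-least-squares ensemble built through the identical SFS
machinery. Ortholog remapping (average many-to-one, drop unmapped,
retrain) carries the ensemble to non-model species.

## Worked example

```python
import chronogauge as cg

# synthetic 4-experiment training study (2 LL + 2 LD, 56 samples,
# 150 rhythmic + 300 background genes) with known ground truth
train, truth = cg.make_training_like(seed=1)
test, _ = cg.make_test_like(seed=1)   # unseen samples, same genes

ens = cg.ChronoGaugeEnsemble(n_runs=10, sfs_budget=60, tuning_trials=3,
                             base_seed=10).fit(train, cg.filter_circadian(truth))
pred = ens.predict(test)              # minutes on [0, 1440)
s = cg.summarize_errors(pred, test.times_min())
print(f"held-out MdAE {s.mdae_min:.1f} min, MAE {s.mae_min:.1f} min")
```

which prints

```
held-out MdAE 29.6 min, MAE 32.0 min
```

— the ensemble recovers the unseen samples' circadian time to ~30
minutes (median), against ~360 minutes expected for uninformed guessing
on the 24-h circle. The same objects expose the interpretation surface:
`ens.predict_samples(test, truth_min=...)` attaches per-sub-predictor
errors and accurate/advanced/delayed fingerprint labels, and
`ens.feature_frequency(prior)` ranks genes by how often the SFS selected
them per phase bin.

A shell workflow is available too:

```bash
chronogauge simulate --seed 1 --out sim/
chronogauge train --expr sim/expression.tsv --meta sim/metadata.tsv \
    --prior sim/prior.csv --runs 10 --seed 0 --out model/
chronogauge predict --model model/ --expr sim/expression.tsv \
    --meta sim/metadata.tsv --out estimates.tsv
```

## Layout

| module | contents |
| --- | --- |
| `timecodec` | cyclic encode/decode, angular loss, circular statistics |
| `io_scaling` | expression matrix + metadata I/O, z-score policies |
| `rhythmicity` | prior loading, Q filter, phase bins, cosinor fallback |
| `nn` | `CyclicMLPRegressor` (the sub-predictor) and circular CV |
| `sfs` | phase-balanced sequential feature selection |
| `ensemble` | `ChronoGaugeEnsemble`, fingerprints, feature frequency |
| `baselines` | `MolecularTimetable`, `PLSCyclicRegressor`, `PLSREnsemble` |
| `crossspecies` | ortholog collapsing and ensemble remapping |
| `synthetic` | ground-truth circadian expression generator |
| `evaluation` | MdAE/MAE summaries, group tests, drift-derived periods |
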