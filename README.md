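# equigait

Equine gait recognition from **rider-worn** accelerometers.

Attaching motion sensors to a horse can cause discomfort and alter its
behaviour, so a practical alternative is to instrument the *rider* and
recover the horse's gait — halt, walk, trot, or canter — from the rider's
tri-axial acceleration signal. How well that works depends on four design
choices: the classification model, the analysis window length, the sampling
rate, and where on the rider's body the sensor sits (knee, backbone, chest,
or arm).

`equigait` implements that study design end to end as a tested pipeline:

* **Simulation** (`equigait.simulate`) — labelled synthetic riding sessions
  with the statistical structure of real mounted recordings: bout-structured
  activity sequences (lognormal durations, 6.3 s median), four gaits with
  distinct stride fundamentals and harmonic signatures, realistic class
  imbalance (walk ≈ 43%, trot ≈ 40%, canter ≈ 14%, halt ≈ 3%), per-horse
  stride/amplitude variability, and four sensor locations with different
  coupling and noise. The four location streams of a horse are rendered from
  the *same* ride, as four simultaneously worn sensors would record.
* **Session I/O** (`equigait.io`) — accelerometer CSV (`timestamp,x,y,z`,
  units of g, x toward the ground) and interval-label files (11 fine
  activities: halt plus collected/medium/normal walk/trot/canter), aligned
  to samples with a half-open `[start, end)` convention.
* **Preprocessing** (`equigait.preprocessing`) — superclass mapping, *pure*
  window extraction (windows never cross a bout boundary), integer
  decimation of 50 Hz streams to 25/10/5 Hz, and per-channel robust scaling
  (median removed, divided by the IQR, fitted on the training split only).
* **Models** (`equigait.models`, `equigait.nn`) — eight neural
  architectures behind one scikit-learn-style estimator
  (`GaitNetClassifier`): an MLP, a CNN, a dilated CNN, a spatial-dropout
  CNN, small and large stacked LSTMs, a WaveNet-style gated dilated network,
  and a convolutional LSTM. They run on a compact numpy engine with explicit
  backpropagation and Adam, so the package has no deep-learning framework
  dependency and training is exactly reproducible from a seed.
* **Evaluation** (`equigait.evaluation`, `equigait.metrics`) — the full
  8 × 13 × 4 × 4 = 1664-configuration grid against a fixed validation horse,
  the average/maximum parameter-selection rules, horse-exclusive
  leave-one-subject-out cross-validation (LOSOCV) with unweighted fold
  means, accuracy and macro F1, Welch's t-test for location comparisons,
  and per-horse/per-gait dataset summaries.

## Worked example

Cross-validate the selected configuration — convolutional LSTM, 4 s windows
at 25 Hz, knee sensor — on the default synthetic cohort (5 horses × 4
locations × 10 min sessions at 50 Hz), holding out each horse in turn:

```python
import equigait as eg
from equigait.models import TrainConfig

cohort = eg.simulate_cohort(eg.CohortConfig(seed=1))
report = eg.losocv(
    cohort, ("conv_lstm", 4, 25, "knee"), TrainConfig(seed=1), min_fraction=0.0
)
for horse, acc, f1 in report.folds:
    print(f"{horse}: accuracy {acc}%  F1 {f1}%")
print("fold mean accuracy:", report.mean_accuracy)
print("fold mean F1:      ", report.mean_f1)
```

prints

```
horse00: accuracy 97.27%  F1 95.68%
horse01: accuracy 98.13%  F1 97.6%
horse02: accuracy 99.14%  F1 99.06%
horse03: accuracy 99.12%  F1 98.06%
horse04: accuracy 98.23%  F1 97.96%
fold mean accuracy: 98.38
fold mean F1:       97.67
```

Each fold trains on four horses and scores the held-out horse's windows, so
the numbers measure generalisation to an unseen horse; the means are
unweighted fold averages. On the reference cohort's published per-fold
results the same aggregation reproduces the study's reported averages (89.72%
including the dominant horse's fold, 98.31% excluding it).

The same pipeline is available from the shell:

```
equigait simulate --seed 1 --out cohort/
equigait grid --manifest cohort/manifest.yaml --axes axes.yaml --out grid.csv
equigait losocv --manifest cohort/manifest.yaml --arch conv_lstm --out cv.json
equigait report --grid-csv grid.csv --out report.md
```

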