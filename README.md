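# fallwin

Smartphone-accelerometer fall detection with sub-window statistical
features. `fallwin` is a library and command-line tool for researchers and
engineers working on wearable-sensor fall-detection systems: it implements
windowed feature extraction from tri-axial acceleration signals, classical
detectors (1-nearest-neighbor and RBF-kernel SVM), class balancing,
subject-aware evaluation protocols, causal streaming detection over long
recordings, and model-agnostic Shapley feature attribution. A built-in
synthetic signal generator makes the whole pipeline runnable and testable
without any dataset download.

## The method

A motion event is a 3 s window of tri-axial acceleration *(x, y, z)* in g,
sampled at 50 Hz (150 samples per axis). The window is split into **m = 2
sub-windows** of 2 s overlapping by 50 % (1 s): the first captures the
onset of a fall (balance loss, a growing oscillation of roughly ±0.5 g),
the second its impact (a brief free-fall dip toward 0 g followed by a spike
of ±1 g and above). From each sub-window, per axis:

- mean μ = (1/n) Σ xᵢ
- median of the sorted sequence
- population standard deviation σ = √((1/n) Σ (xᵢ − μ)²)
- skewness (1/n) Σ (xᵢ − μ)³ / σ³
- kurtosis (1/n) Σ (xᵢ − μ)⁴ / σ⁴ (non-excess)
- maximum, minimum

plus one 3-axis **slope** SL = √(Δx² + Δy² + Δz²), where Δ is the per-axis
max − min range. That is 7 × 3 + 1 = 22 features per sub-window, i.e. a
**44-dimensional vector** for the default scheme (22·m in general). The
vector is z-scored and fed to a 1-NN or RBF-SVM (γ = 1/(n_features·Var X))
detector. Because fall events are rare, training folds are rebalanced with
SMOTE; evaluation uses k-fold, 30-fold or leave-one-subject-out (LOSO)
cross-validation with metrics accuracy, macro-average accuracy
(MAA = mean of per-class accuracies), sensitivity, specificity, precision
and F1. On continuous recordings a sliding window classifies causally — the
decision for window *t* with hop *H* and length *W* is available at
*tH + W*, never later — and a sample or stream is labeled FALL iff **any**
window is (the OR rule, prioritizing sensitivity).

## Worked example

```python
from fallwin import (ModelSpec, StreamConfig, SyntheticConfig, WindowScheme,
                     balance_training_set, fit, gen_continuous_recording,
                     gen_event_dataset, make_folds, run_cv,
                     streaming_evaluate)

# 10 subjects, 200 falls / 800 ADLs of 3 s @ 50 Hz, +-2 g
cfg = SyntheticConfig(n_subjects=10, falls_per_subject=20,
                      adls_per_subject=80, seed=42)
data = gen_event_dataset(cfg).to_labeled_features()

plan = make_folds(data, "loso")
result = run_cv(data, plan, ModelSpec(kind="knn"), use_smote=True, seed=42)
pooled = result.pooled_metrics
print(f"LOSO 1-NN over {data.n_rows} events: "
      f"sensitivity {pooled.sensitivity:.4f}, "
      f"specificity {pooled.specificity:.4f}, "
      f"mean accuracy {result.mean['accuracy']:.4f}")

detector = fit(balance_training_set(data, seed=42),
               ModelSpec(kind="knn"), seed=42)
recording = gen_continuous_recording(cfg, duration_s=1200, n_falls=1, seed=1)
stream = streaming_evaluate(recording, detector, WindowScheme(),
                            StreamConfig(window_s=3.0, overlap=0.5))
print(f"streaming: {len(stream.window_decisions)} windows, "
      f"{len(stream.alarms)} alarms, "
      f"event sensitivity {stream.sensitivity:.2f}, "
      f"window specificity {stream.specificity:.4f}")
```

prints

```
LOSO 1-NN over 1000 events: sensitivity 0.9950, specificity 1.0000, mean accuracy 0.9990
streaming: 799 windows, 3 alarms, event sensitivity 1.00, window specificity 0.9975
```

Read: testing on held-out subjects, the 1-NN detector recovers 199 of the
200 synthetic falls with no false alarm among the 800 daily activities;
streamed over an annotated 20-minute recording it alarms inside the one
true fall interval and raises false alarms on 2 of the 797 non-fall
windows.

The same pipeline is available from the shell:

```
fallwin simulate --mode events --out-dir data/ --seed 42
fallwin extract  --manifest data/manifest.csv --out features.csv
fallwin eval     --features features.csv --mode loso --model knn --seed 42 --out report.json
fallwin train    --features features.csv --model knn --out model.bin
fallwin stream   --trace rec.csv --model model.bin --overlap 0.5 --out stream.json
fallwin sweep    --axis o --out sweep.csv
fallwin explain  --model model.bin --features probes.csv --background features.csv --out attr.csv
```

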