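# emophys

Emotion classification from inexpensive wearable physiology: a
single-channel EEG band-power stream and a PPG-derived inter-beat
interval (IBI) stream, labelled on the Arousal–Valence plane from SAM
(Self-Assessment Manikin) self-reports.

The package is aimed at affective-computing researchers who want a
tested, reproducible reference for the full chain:

1. **Feature extraction** — 36 physiological indexes per second:
   22 EEG (8 sensor bands, 3 composite bands α/β/γ, and a 15-sample
   moving average of each) and 14 HRV (IBI, HR, pNN10–pNN50, SDNN,
   RMSSD, SDNN/RMSSD, CVNN over a 30-beat sliding window; LF, HF,
   LF/HF over a trailing 200-s spectral window).
2. **Labeling** — High arousal/valence iff SAM score ≥ 5; four
   quadrant classes HAHV/HALV/LALV/LAHV; three tasks (4-class,
   binary arousal, binary valence).
3. **Ensemble feature selection** — every feature scored by four
   algorithms: correlation ratio η² (between-class SS / total SS),
   plug-in mutual information I(X;Y) = Σ p(x,y) log p(x,y)/(p(x)p(y))
   after equal-frequency binning, Gini impurity-decrease importance of
   a 1000-tree random forest, and mean |w| of an L1-regularised linear
   SVM (C = 1). Scores are min-max normalised, averaged, and the top
   10 selected.
4. **Evaluation** — 21 feature groups (6 fixed families + 15 top-10
   lists) × 3 tasks, each scored by a feed-forward network (three
   256-unit ReLU layers, softmax, SGD, dropout 0) under stratified
   10-fold cross-validation with Macro F1
   (the unweighted class mean of 2·precision·recall/(precision+recall)),
   against a uniform-random no-learning baseline.

Because participant recordings of this kind are not redistributable, a
synthetic study generator with planted, per-quadrant class structure
(IBI mean shifts, 0.1/0.3 Hz IBI modulation for LF/HF power, EEG band
shifts) provides ground truth for testing and for the reproduction
script. See `docs/methods.md` for the model and all numerical choices.

## Worked example

```python
from emophys import (SimConfig, simulate_study, EmotionStudy,
                     FeatureGroup, ModelSpec, train_eval)
from emophys.labeling import task_labels

study = simulate_study(SimConfig(n_participants=25, seed=1))
model = EmotionStudy.from_study(study)          # extract 36 features + labels

ranking = model.rank("quadrant", k=10, seed=1)  # 4-algorithm ensemble
print(ranking.top_k)

group = FeatureGroup(7, "ENSEMBLE (quadrant)", tuple(ranking.top_k))
y = task_labels(model.labels, "quadrant")
result = train_eval(model.features, y, group, "quadrant",
                    ModelSpec(seed=1), k=10, seed=1)
print(f"mean Macro F1 = {result.mean:.4f} (sd {result.std:.4f})")
```

Output:

```
['ibi', 'hr', 'lf_hf', 'lf', 'hf', 'sdnn_rmssd', 'cvnn', 'rmssd', 'ma15_mid_gamma', 'pnn50']
mean Macro F1 = 0.9999 (sd 0.0003)
```

The ensemble ranks the heart-derived indexes first — the default
synthetic study plants its strongest class structure in the IBI mean
and its LF/HF modulation, with a weaker planted shift on the mid-γ EEG
band (picked up at rank 9) — and the 4-class quadrant model built on
those 10 features is essentially perfect under 10-fold CV, as expected
for a strong planted effect. `model.fit()` runs all 21 groups × 3
tasks and returns a results object with `summary()`, `best(task)`,
`save(dir)` and `plot(task)`.

The same steps are available from the shell:

```bash
emophys simulate --out streams/ --seed 1
emophys extract  --streams streams/ --out features.csv
emophys label    --sam streams/sam.csv --out labels.csv
emophys select   --features features.csv --labels labels.csv --task quadrant --out ranking.json
emophys evaluate --features features.csv --labels labels.csv --out report/
```

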