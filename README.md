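# korosound

Signal processing and classification for **Korotkoff sounds (KS)** — the
pulse-synchronous sounds heard over the brachial artery while a blood-pressure
cuff deflates. Because KS is trivially cheap to record during a routine
blood-pressure measurement, its time–frequency structure is an attractive
candidate for *noninvasive pre-screening of chronic heart failure (CHF)*:
reduced cardiac output changes both the spectral energy distribution of the
pulses and their beat-to-beat variability.

The package implements the full processing chain a study of this kind needs,
plus a ground-truthed synthetic-record generator so every stage can be
validated without access to clinical data:

1. **Denoising** — short-time spectral Wiener filter. The noise power spectrum
   is estimated from the silent lead-in of the recording (before the first
   Korotkoff sound); gains follow the decision-directed a-priori SNR rule.
2. **Segmentation** — normalized Shannon energy envelope
   `E_j = −(1/N) Σ z_i² ln z_i²` over 40 ms frames with 50 % overlap,
   standardized to `P_j = (E_j − mean)/std`. Pulses ("anchors") are local
   maxima with `P ≥ 0.2·max(P)`; anchors closer than 100 ms are merged;
   isolated friction clicks are rejected against the quasi-periodic train;
   the record span is `[first anchor − 300 ms, last anchor + 500 ms]`.
3. **Features (46)** — at the 800 Hz working rate a 3-level wavelet-packet
   decomposition yields eight exact 50 Hz bands. 19 energy features: the seven
   global band ratios `S_total(j) = E(j)/E_total(50–400)` plus the spread and
   extrema of the per-beat series `en = E(50–100)/E(50–400)`,
   `en_h = E(150–400)/E(50–400)`, mean-normalized total energy `Ep` and
   inter-beat interval `TM`. 12 statistical features, 2 entropies, and 13
   MFCCs (DCT of log Mel filter-bank energies, orders 1–13).
4. **Classification** — an RBF-kernel SVM whose penalty `c` and kernel scale
   `g` are selected by Bayesian optimization (Gaussian-process surrogate,
   expected improvement) of 10-fold cross-validated accuracy, compared against
   eleven standard presets (fine/medium/coarse decision trees, fine/medium/
   cosine KNN, Gaussian/kernel Naive Bayes, AdaBoost/bagged/RUSBoost
   ensembles) under a stratified 80/20 protocol with feature sets
   A (energy+statistical+entropy), B (statistical+entropy+MFCC), C (all).
5. **Valsalva analysis** — for a paired normal-state / maneuver recording,
   the percent variation `V = (Ns − Vm)/Ns × 100` of each energy feature.

## Worked example

```python
import korosound as ks

# generate a synthetic cuff recording and inspect it
record, beat_times = ks.generate_record(ks.healthy_spec(), seed=42)
print(f"duration {record.duration:.1f} s, {len(beat_times)} beats")

features = ks.extract_features(record)
print(f"S_total(50-100) = {features.values['Stotal_50_100']:.1f} %")
print(f"std_enr = {features.values['std_enr']:.2f}, "
      f"std_TM = {features.values['std_TM']:.2f}")

# a labeled cohort and the classifier grid on feature set C
records, _ = ks.generate_cohorts(25, ks.healthy_spec(), ks.chf_spec(), seed=7)
table = ks.features_table(records)
report = ks.run_experiment(table, feature_sets=("C",),
                           families=["knn_fine", "bo_svm"], seed=7,
                           cv=5, bo_iter=10)
cell = report.results["C"]["bo_svm"]
print(f"BO-SVM: test Acc {cell['metrics']['Acc']:.2f}, "
      f"CV acc {cell['cv_score']:.2f}, "
      f"c = {cell['hyperparams']['c']:.3g}, g = {cell['hyperparams']['g']:.3g}")
```

prints

```
duration 23.4 s, 22 beats
S_total(50-100) = 89.2 %
std_enr = 6.26, std_TM = 6.35
BO-SVM: test Acc 1.00, CV acc 1.00, c = 147, g = 0.459
```

The 22-beat record concentrates 89 % of its 50–400 Hz energy in the 50–100 Hz
band (the impact component of each pulse dominates), with ~6 % beat-to-beat
spread in the low-frequency ratio and interval series. On the programmed
healthy/CHF contrast the optimized SVM separates the held-out records
perfectly; the selected hyperparameters are the best of the optimizer's
cross-validated evaluations.

The same workflow is available from the shell:

```bash
korosound simulate --preset healthy --n 20 --seed 7 --out data/healthy
korosound extract data/healthy/manifest.csv --out features.csv
korosound segment data/healthy/healthy-000.wav --out seg.json
korosound train features.csv --set C --model bo_svm --seed 7 --out model.json
korosound valsalva before.wav after.wav --out table.csv
```

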