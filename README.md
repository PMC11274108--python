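# pdmotion

Estimating Parkinson's disease motor severity (UPDRS-III) from wrist- and
ankle-worn gyroscopes during unscripted daily activities.

Clinicians rate motor severity with the UPDRS Part III exam — an in-clinic,
episodic snapshot. Wearable gyroscopes capture the underlying motor signs
(4–6 Hz tremor, the reduced low-frequency movement amplitude of
bradykinesia) continuously and unobtrusively. `pdmotion` implements a
complete pipeline that turns two-site, six-channel gyroscope recordings
into round-level UPDRS-III estimates, for researchers working on digital
biomarkers of Parkinson's disease:

1. **Preprocessing** — linear-phase band-pass FIR (3 dB points at 0.5 and
   15 Hz, 513 taps, applied forward–backward), segmentation into
   non-overlapping 5 s windows x_r (320 × 6 at 64 Hz) that never straddle
   a clinical-exam exclusion or round boundary, and per-window one-sided
   dB-magnitude STFT spectrograms x_s (1 s Kaiser window, 90 % overlap →
   33 × 43 × 6).
2. **Self-supervised pretext learning** — each unlabeled window spawns
   three transformed copies (random 3D rotation per sensor, segment
   permutation, smooth monotone time-warp). A dual-branch CNN (1D ConvR on
   x_r, 2D ConvS on x_s; shared 128-unit task layer per transformation)
   learns to recognize which transformation was applied by minimizing a
   weighted multi-task binary cross-entropy
   L = Σ_t α_t · BCE_t(y_p, P_t).
3. **Transfer and fine-tuning** — the pretext-trained convolutional
   weights are copied into a multichannel CNN-LSTM regressor (one 128-unit
   LSTM per branch over the intra-window convolutional sequence, fused by
   concatenation → dense 256 → linear), the first convolutional blocks are
   frozen, and the rest is fine-tuned against round-level clinical scores
   with a Huber loss (δ = 1).
4. **Evaluation** — leave-one-subject-out (or subject-grouped k-fold)
   cross-validation; per-window estimates are averaged within each
   clinical round and compared to the clinician's score with Pearson r,
   R², MAE and RMSE, with breakdowns by activity and medication state.
   A seven-variant supervised model ladder (1D/2D/multichannel CNN and
   CNN-LSTM) provides baselines.

Because clinical cohorts of this kind are private, the package ships a
**synthetic cohort simulator** (`pdmotion.simulate`) that emulates the
study protocol — 24-style mixed cohorts with an OFF-state first round
(scores 12–60), ON-state later rounds (4–38), optional end-of-session
wear-off, seven scripted activities of daily living, and per-round
clinical-exam exclusion stretches — with severity-dependent tremor power
and bradykinetic amplitude reduction, so every stage of the pipeline is
testable end to end.

The neural-network layer (`pdmotion.nn`) is a compact, self-contained CPU
engine in numpy: 1D/2D convolutions, max/global pooling, dropout, LSTM,
manual backpropagation, and Adam with per-parameter freeze flags.

## Worked example

```bash
pdmotion simulate --n-subjects 8 --seed 1 --out-dir data/ --round-duration 90
pdmotion preprocess --data-dir data/ --out windows.h5 --seed 1
pdmotion evaluate --windows windows.h5 --variant cnn_multi_lstm \
    --out report.json --seed 1 --n-folds 3 --epochs 30 --reduced
```

The three stages print JSON-lines progress logs; this exact invocation
prints:

```
{"stage": "simulate", "elapsed_s": 1.17, "n_subjects": 8, "out_dir": "data/", "files": 8, "seed": 1}
{"stage": "preprocess", "elapsed_s": 1.15, "n_windows": 364, "out": "windows.h5"}
{"stage": "evaluate", "elapsed_s": 72.01, "variant": "cnn_multi_lstm",
 "r": 0.9176914327258643, "mae": 3.5274683145376353, "out": "report.json"}
```

`report.json` contains the pooled round-level metrics — here Pearson
r ≈ 0.92 between estimated and simulated clinical scores over the 28
held-out rounds, MAE ≈ 3.5 UPDRS-III points — plus per-subject reports and
activity/medication-state breakdowns, and `report.predictions.csv` holds
the per-window estimates. `--reduced` runs the width-reduced desk-scale
recipe sized for a laptop CPU; omit it for the full published widths if
you have the compute. Swap `--variant mssl_cnn_multi_lstm` for the
self-supervised pipeline (pretext pretraining → transfer → fine-tuning;
see `docs/methods.md` for why frozen transfer underperforms at reduced
width on synthetic cohorts), or use `pdmotion benchmark` to run all seven
variants over the same folds and write a comparison table. Standalone
`pdmotion pretrain` / `pdmotion finetune` subcommands train over a whole
window store and exchange weights through HDF5 bundles, for workflows that
manage their own splits.

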