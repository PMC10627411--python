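# bruganet

Representative-beat ECG fusion and dense neural-network screening for
the hidden electrocardiographic signature of Brugada syndrome (BrS).

BrS is an inherited arrhythmic cardiomyopathy that can cause sudden
cardiac death while leaving the routine ECG apparently normal; the
diagnostic "type 1" pattern often appears only under a risky sodium
channel blocker (ajmaline) challenge. This package implements, end to
end, a noninvasive screening approach for researchers in computational
electrophysiology: reduce a noisy multi-lead baseline ECG to one
high-signal-to-noise representative heartbeat per lead, fuse the beats
into a single vector, and train a small dense neural network to predict
the drug-challenge outcome, together with the full
diagnostic-statistics layer a clinical validation would report. A
seeded synthetic ECG generator provides labeled cohorts with known
ground truth for every stage.

## Method

Per lead, the pulse train is reduced by: Pan–Tompkins-style R-peak
detection (band-pass 5–25 Hz, derivative, squaring, moving-window
integration, adaptive threshold, refinement to the raw extremum);
segmentation into windows spanning R − 300 ms to R + 450 ms; rejection
of beats with Pearson correlation < 0.90 against a median template or
peak amplitude off by more than 2×; pointwise averaging (residual noise
shrinks as σ/√N); and resampling to 150 samples at 200 Hz with the R
fiducial at sample 60. The nine canonical leads (L1, L2, derived III,
V1–V6; unipolar limb leads excluded) concatenate into the fused trace
x ∈ ℝ¹³⁵⁰, one row of the design matrix X.

The classifier F(x) = ŷ ∈ (0, 1) is three hidden blocks of
[dense → Gaussian noise → ReLU → batch norm] and a sigmoid output,
trained with Adam on binary cross-entropy (pure numpy implementation,
exact input gradients). Validation follows a leave-one-out scheme
wrapping stratified 7-fold ensembles: each patient is scored by the
mean of 7 models trained without them. Reported statistics: Youden's J
threshold, sensitivity/specificity/PPV/NPV/accuracy from confusion
counts, Mann–Whitney AUC with DeLong confidence intervals, and
two-sided χ²/Fisher comparisons of proportions. Feature importance over
the 1350 positions comes from gradient saliency (mean |∂ŷ/∂x|) with a
permutation-importance cross-check.

## Worked example

```python
import bruganet as bn
from bruganet.evaluate import (youden_threshold, confusion_counts,
                               binary_metrics, delong_interval,
                               mann_whitney_auc)

# 60 synthetic patients, half carrying a 0.3 mV ST-segment effect in V1-V3
spec = bn.CohortSpec(n=60, duration_s=20.0, effect=0.3, prevalence=0.5, seed=7)
records, y, _ = bn.synthesize_cohort(spec)

X, ids = bn.preprocess_cohort(records)        # (60, 1350) fused traces
est = bn.DenseNoiseClassifier(hidden_sizes=(32, 32, 32), max_epochs=120,
                              patience=15, batch_size=32)
ens = bn.FoldEnsembleClassifier(estimator=est, random_state=3).fit(X, y)

auc = mann_whitney_auc(ens.oof_scores_, y)    # held-out (out-of-fold) scores
thr, j = youden_threshold(ens.oof_scores_, y)
m = binary_metrics(confusion_counts(ens.oof_scores_, y, thr))
r = delong_interval(ens.oof_scores_, y)
print(f"held-out AUC {auc:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f})")
print(f"Youden threshold {thr:.3f} (J={j:.2f}); "
      f"sens {m['sensitivity']:.1%}, spec {m['specificity']:.1%}, "
      f"acc {m['accuracy']:.1%}")
```

Output:

```
held-out AUC 1.000 (95% CI 1.000-1.000)
Youden threshold 0.481 (J=1.00); sens 100.0%, spec 100.0%, acc 100.0%
```

At this effect size (0.3 mV, about three times the clinical 1 mm
criterion's resolution) and low noise, the synthetic classes are fully
separable, so every held-out patient is classified correctly; the AUC
falls toward 0.5 as the `effect` knob approaches 0 (that null
calibration is one of the package's own checks). On a zero-effect
cohort the same leave-one-out machinery stays at chance — the built-in
leakage detector.

The same pipeline is available from the shell:

```bash
bruganet simulate  --seed 5 --out raw/
bruganet preprocess --inputs raw/ --dialect claris --out fused/
bruganet train     --seed 1 --fused fused/fused.tsv --out model/
bruganet evaluate  --fused fused/fused.tsv --model model/ensemble.npz --out report/
bruganet importance --fused fused/fused.tsv --model model/ensemble.npz --out imp.tsv
```

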