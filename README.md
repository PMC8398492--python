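# boldwct

Wavelet-coherence scalogram classification of autism-spectrum subtypes from
resting-state fMRI ROI time series.

## The problem

Resting-state fMRI studies of autism usually classify patients against
controls from *static* functional connectivity — one correlation coefficient
per node pair over the whole scan. Static features plateau well below
clinically useful accuracy, and they say nothing about the DSM-4 subtypes
(autistic disorder ASD, Asperger's APD, PDD-NOS). This package implements a
*dynamic* connectivity pipeline for multi-site ROI BOLD cohorts (e.g.
116-node AAL parcellations at TR = 2 s, truncated to a common 145 time
points):

1. **Node selection.** For every node, estimate the Welch power spectral
   density of its BOLD signal, z-score each subject's PSD values jointly over
   nodes × frequencies (removing site scale), average over frequency, and run
   a one-way ANOVA across diagnostic groups. Nodes with p ≤ 0.05 are ranked
   by ascending p; the top node seeds the connectivity step.
2. **Dynamic connectivity.** For the seed node against each of the other
   nodes, compute squared wavelet coherence

   `WCT_xy(a,b) = |S(W_x*(a,b) W_y(a,b))|² / ( S(|W_x|²) · S(|W_y|²) )`,

   where `W` is the continuous wavelet transform with a complex Morlet mother
   wavelet (ω₀ = 6, so the Fourier-period/scale ratio is
   4π/(ω₀+√(2+ω₀²)) ≈ 1.03) and `S` smooths in time and scale. Each
   coherence map is rendered as a 224 × 224 RGB scalogram image — 115 images
   per subject on the 116-node atlas.
3. **Classification.** A 3-block CNN (3×3 convolutions, ReLU, 2×2 max
   pooling; dense softmax head) classifies the scalograms, binary
   (patient vs. control) or 4-class (ASD / APD / PDD-NOS / NC), trained with
   batch size 32, 20 epochs, learning rate 5·10⁻⁴, and a choice of
   Adam / SGDM / RMSprop.
4. **Evaluation.** Precision, sensitivity, specificity, accuracy and F-score
   (in percent), macro-averaged for multi-class, under stratified hold-out
   (0.7/0.15/0.15), stratified k-fold, or leave-one-site-out protocols.

Because public multi-site data cannot ship with the package, a synthetic
cohort generator (`boldwct.synthetic`) produces BOLD-like multi-site signals
with *planted* group effects — per-group spectral power at one node and
per-group phase coupling to a partner-node subset — so every stage of the
pipeline is testable end to end.

## Worked example

```python
import boldwct as b
from boldwct.pipeline import ExperimentConfig, run_experiment

spec = b.CohortSpec(n_per_group=8, n_nodes=12, planted_node=3,
                    partner_nodes=tuple(j for j in range(12) if j != 3)[:8],
                    rng_seed=7)
cfg = ExperimentConfig(
    classes=("ASD", "NC"), cohort_spec=spec,
    coherence_config=b.CoherenceConfig(image_size=(32, 32)),
    cnn_config=b.CnnConfig(filters_per_block=(4, 8, 16), input_shape=(32, 32, 3)),
    train_config=b.TrainConfig(epochs=8, batch_size=16),
    out_dir="run", master_seed=7)
res = run_experiment(cfg)
print("top-ranked node:", res.ranking.top_node)
print(res.report.to_frame().to_string())
```

prints

```
top-ranked node: 3
       precision  sensitivity  specificity  accuracy  f_score
ASD         83.3         76.9         84.6      80.8     80.0
NC          78.6         84.6         76.9      80.8     81.5
macro       81.0         80.8         80.8      80.8     80.7
```

The ANOVA ranking recovers the planted node (index 3), and the CNN separates
the two groups' coherence scalograms at 80.8% test accuracy against a 50%
chance level — the planted coupling difference (0.9 vs. 0.1 mixing weight,
i.e. band coherence ≈ 0.81 vs. ≈ 0.01) is what the images encode. The run
directory contains the ranking CSV, scalogram manifest, metric reports,
confusion matrix, model checkpoint and a provenance record of every resolved
default and derived seed.

The same machinery is available from a shell:

```sh
boldwct simulate --out cohort --n-per-group 8 --nodes 12 --seed 7
boldwct rank --manifest cohort/manifest.csv --out ranking.csv
boldwct run-binary --out run --seed 7
```

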