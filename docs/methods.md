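# Methods

`sersnet` reimplements, as a tested and reusable package, a deep-learning
pipeline for classifying dendritic-cell (DC) maturation from label-free
single-cell surface-enhanced Raman spectroscopy (SERS). The original
acquisition — several hundred live DCs carrying gold-nanoparticle SERS
substrates, tens of replicate spectra per cell — is not publicly deposited,
so the package couples the analysis to a first-class synthetic-data
generator that reproduces the statistical structure the analysis assumes.
This note records the models, the defaults and why they were chosen, and
what the synthetic benchmarks do and do not demonstrate.

## Synthetic single-cell SERS model

A spectrum is simulated on a shared wavenumber axis as

    s(w) = b(w) + g_c * sum_k a_{c,k} G_k(w) + eps(w)

* **Axis.** Uniform, 600–1700 cm^-1 with 1015 points (spacing ≈ 1.09
  cm^-1). The range covers every catalog band; the length is the input
  size the convolutional architecture is dimensioned for (a kernel-3,
  stride-1 valid convolution of a 1015-point spectrum yields 1013
  features, then 506 after 2×2 max pooling).
* **Band catalog** `G_k`: Gaussian lines (default FWHM 12 cm^-1, a typical
  SERS bandwidth) at the literature-assigned biomolecular bands:
  methionine 647, O–P–O of DNA 826, phenylalanine 1000, ribose C–O 1018,
  carbohydrates 1025, protein C–C/C–N 1161, tyrosine 1206, fatty acid
  1444, COO⁻ 1562, tryptophan 1623 cm^-1.
* **Class effect.** Each class (mature/immature) has per-band mean
  amplitudes. Maturation is dominated by tryptophan: the default
  mature/immature amplitude ratio is 3.0 at 1623 cm^-1, 1.15 at 826 and
  1161 cm^-1, and 1.0 elsewhere. These effect sizes were chosen once so
  that the downstream statistics reproduce the qualitative findings the
  pipeline is built to detect (a dominant 1623 cm^-1 contribution; a
  strongly separated 1623/1025 ratio); they are fully configurable.
* **Cell hierarchy.** Per cell-and-band amplitudes `a_{c,k}` are drawn
  N(mean, sd) with sd = 10% of the mean (clipped at 0), and each cell has a
  multiplicative log-normal scale `g_c` (sd 0.15) modeling
  nanoparticle-uptake variation. All replicate spectra of a cell share
  these draws, so within-cell variance is smaller than between-cell
  variance — the structure that makes cell-level splitting matter.
* **Baseline** `b(w)`: a small positive quadratic in the reduced coordinate
  (coefficients 0.05, 0.03, 0.02), standing in for substrate background. No
  explicit baseline-correction stage exists; normalization and learning
  absorb it.
* **Noise** `eps`: i.i.d. Gaussian, sd 0.02 on the O(1) amplitude scale.
* **Design sizes.** 196 mature + 210 immature cells at 50 spectra per cell
  (20,300 spectra) — the study's cell counts, with replicates chosen to
  match its ≈20,000-spectrum corpus.

**Time-course.** Treated cells interpolate their band-amplitude means from
the immature toward the mature profile with a non-decreasing progress
weight per time point; control cells stay immature. Defaults: 2/4/6 h with
weights (0.5, 0.8, 1.0) — maturation well underway by 2 h, complete by
6 h. Per-cell random effects are drawn once and reused across time points
(cell identities persist); only acquisition noise is redrawn, so a treated
cell's tryptophan intensity rises monotonically in expectation.

**Mapping grids.** One spectrum per node of a rows×cols grid at 1 µm
spacing; nodes within 0.35·min(rows, cols) of the center carry one
simulated cell's spectrum, the periphery carries baseline-only background.

**What the generator does not emulate:** cosmic rays and detector
artifacts, wavenumber miscalibration, band-shape asymmetry and shifts,
correlated (1/f or baseline-drift) noise, intra-cell spatial heterogeneity,
and any biochemical covariance between bands beyond the shared cell scale.
Passing benchmarks therefore demonstrate that the pipeline recovers the
structure it assumes, at realistic effect sizes — not performance on real
instruments' data.

## Preprocessing

* **Max-min normalization**, per spectrum, to [0, 1]; constant spectra map
  to zero. Per-spectrum scope is the standard reading and makes
  intensities comparable across cells with different uptake; it also makes
  every downstream statistic invariant to global intensity rescaling.
* **Per-cell averaging** for single-cell models: the arithmetic mean of a
  cell's replicate spectra (labels must agree within a cell).
* **Confidence bands**: pointwise Student-t intervals for the mean
  spectrum.
* **Splitting**: 70/20/10 train/validation/test with largest-remainder
  rounding (ties toward the earlier subset — deterministic), seeded
  shuffling, stratification by label on by default. Granularity is
  configurable: `unit="cell"` (default) keeps all replicates of a cell in
  one subset, preventing leakage of cell identity across subsets;
  `unit="spectrum"` replicates the multicell protocol that splits
  individual spectra.

## Models and training

The CNN is:
conv1d(32 filters, kernel 3, stride 1, valid) → ReLU → dropout →
maxpool1d(2, stride 2) → flatten → dense(32, ReLU, L2) → dense(1) with a
sigmoid output. For a 1015-point spectrum the shapes are 1013×32 (128
conv parameters), 506×32 after pooling, 16,192 flattened. Baselines: an
MLP (one hidden layer of 64 ReLU units) and a DNN (three hidden layers of
128 ReLU units with dropout) — conventions adopted for the comparison
experiment, since only the CNN is fully specified.

Training: 50 epochs of mini-batch (32) SGD with learning rate 0.01 and
momentum 0.9 on binary cross-entropy, with a reduce-on-plateau scheduler
monitoring validation loss (patience 10, floor 1e-5). Where the recipe
leaves gaps, the defaults are: dropout rate 0.25, L2 coefficient 1e-4,
scheduler factor 0.5 — all configurable. `mature` is encoded as the
positive class, so sensitivity is mature-class recall.

The layers, optimizer and scheduler are implemented in numpy
(`sersnet._nn`), float32, with Glorot-uniform initialization from the run
seed. The sigmoid is fused into the loss for numerical stability at
training time and applied explicitly at inference. Runs are deterministic
for a fixed seed on a fixed platform (one `numpy.random.Generator` drives
initialization, shuffling and dropout); bit-exact reproducibility across
BLAS builds is not promised, statistical reproducibility is.

Evaluation reports confusion counts at threshold 0.5 (ties predict the
positive class), accuracy, sensitivity, specificity, the full ROC (all
thresholds, via scikit-learn) and the trapezoidal AUC, which equals the
pairwise-concordance (rank) formulation — asserted against a brute-force
oracle in the tests. With a single-class evaluation set the AUC is
undefined and reported as null while the threshold metrics are retained.

## Interpretation

* **Band intensity**: mean normalized intensity over a ±6 cm^-1 window
  (matching the default FWHM of 12 cm^-1).
* **Ratio marker**: per-cell 1623/1025 cm^-1 (tryptophan/carbohydrate)
  intensity ratios compared between groups by Welch's two-sided t-test
  (Mann–Whitney available). Non-positive denominators are an error naming
  the offending cell; two groups with zero variance and equal means report
  statistic 0, p = 1.
* **Peak contributions.** "Final-layer weights" are underdetermined for a
  model whose last layer sees flattened pooled features rather than
  wavenumbers, so two methods are provided and cross-checked. The default,
  *occlusion*, zeroes each band's window in every spectrum and records the
  drop in balanced accuracy (negative drops clipped to zero);
  *weight back-projection* propagates absolute weights from the output
  layer back through the dense, flatten, pooling and convolution index
  maps onto input bins and sums them per band window. Both are normalized
  to percent; an entirely uninformative model reports a uniform share. The
  two methods correlate positively on default runs but are not expected to
  agree numerically, and percent contributions are data- and
  model-dependent; no specific printed percentage is treated as a
  reproduction target.
* **Channel images**: band-intensity matrices over mapping-grid positions,
  NaN at absent nodes; **probability heatmaps**: ordered per-sample tables
  of probability, true and predicted label.

## Pipeline, seeds, persistence

`run_experiment` derives stage seeds from one run seed (data = seed,
split = seed+1, model/training = seed+2) and persists every intermediate —
normalized spectra + metadata sidecar, split manifest, training curves,
per-subset metrics JSON, contribution and per-cell ratio CSVs, model
weights (npz + json sidecar) and a run report with config hash and package
version — so every reported number is recomputable from disk (asserted in
the tests). The time-course experiment defaults to one model per time
point (the per-time-point confusion matrices suggest this reading); a
shared-model mode (one model trained on the pooled training splits) is
provided because the protocol is ambiguous. The `sersnet` CLI is a thin
wrapper; training and evaluation are reached through `run`, which persists
everything a separate train/evaluate invocation would need.

## Problem sizes for the shipped benchmarks

The acceptance script recomputes the headline quantities with 5-seed
medians. The architecture checks are exact. The single-cell sensitivity
and the ratio test run at the full 196+210-cell design (cheap, since the
single-cell model trains on 406 averaged spectra). The multicell and
time-course trainings run on reduced replicates of the default generator —
96+104 cells × 25 spectra with 15 epochs, and 60+60 cells × 20 spectra per
time point with 15 epochs — chosen once as the smallest designs that
preserve the default effect sizes, noise and hierarchy while keeping a
single-CPU run practical; the per-class separation, not the corpus size,
drives these metrics. The test suite uses further-miniaturized replicates
of the same generator at unchanged thresholds.

## Known limitations

* The numpy engine is CPU-only and single-threaded beyond BLAS; it
  implements exactly the layers this architecture needs.
* Synthetic benchmarks bound what can be claimed: the study's real-data
  accuracies are not reproducible without the original corpus, and all
  simulation targets measure recovery of generated structure.
* No baseline correction, cosmic-ray removal or wavenumber calibration;
  inputs are assumed clean and on a common axis.
* The DNN/MLP baselines are conventions, not reconstructions.
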