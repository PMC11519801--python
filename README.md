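# sersnet

Label-free classification of dendritic-cell (DC) maturation from
single-cell surface-enhanced Raman spectroscopy (SERS), with a 1-D
convolutional neural network and band-level interpretation.

Mature and immature DCs differ biochemically in ways that imprint on their
Raman fingerprint — most prominently an elevated tryptophan band at
1623 cm⁻¹ in mature cells. Given collections of single-cell SERS spectra
(shared wavenumber axis, per-spectrum cell ids and labels), this package

* simulates seeded synthetic datasets with the hierarchical structure of
  such acquisitions (per-cell amplitude and uptake effects, Gaussian bands
  at assigned biomolecular wavenumbers, substrate baseline, noise),
  including maturation time-courses and mapping grids — the original
  corpus is not publicly deposited, so the generator makes every stage
  testable end to end;
* preprocesses spectra the way the protocol prescribes: per-spectrum
  max-min normalization to [0, 1], per-cell averaging for single-cell
  models, pointwise 95% confidence bands, and a seeded, stratified
  70/20/10 split at spectrum or cell granularity;
* trains the CNN — conv1d(32 filters, kernel 3, stride 1) → ReLU →
  dropout → maxpool(2, 2) → flatten → dense(32, ReLU, L2) → dense(1,
  sigmoid); for a 1015-point spectrum: 1013 conv features (128
  parameters), 506 pooled — for 50 epochs of mini-batch (32) SGD
  (lr 0.01, momentum 0.9) on binary cross-entropy, with a
  reduce-on-plateau scheduler (patience 10, floor 1e-5), plus DNN and MLP
  baselines;
* evaluates with confusion counts (mature = positive), accuracy,
  sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), full ROC and
  trapezoidal AUC;
* interprets models per Raman band: occlusion and weight-back-projection
  contributions, the per-cell I(1623)/I(1025) tryptophan/carbohydrate
  ratio with Welch's t-test (the proposed maturation marker), channel
  images of mapping grids, and per-sample probability heatmaps;
* orchestrates everything (including the 2/4/6 h time-course experiment)
  behind `run_experiment` / `run_timecourse` / `compare_algorithms` and a
  thin `sersnet` CLI, persisting every intermediate as plain text.

The neural layers, SGD-with-momentum and the scheduler are implemented in
numpy (`sersnet._nn`); no deep-learning framework is required.

## Worked example

```python
from sersnet import (RunConfig, SplitSpec, SyntheticConfig, TrainConfig,
                     run_experiment)

config = RunConfig(
    synthetic=SyntheticConfig(n_cells=(48, 52), spectra_per_cell=12),
    split=SplitSpec(unit="spectrum"),   # the multicell protocol
    train=TrainConfig(epochs=10),
    seed=1,
)
report = run_experiment(config)
ev = report.evaluations["test"]
print(f"test: n={ev.n} accuracy={ev.accuracy:.4f} "
      f"sensitivity={ev.sensitivity:.4f} specificity={ev.specificity:.4f} "
      f"auc={ev.auc:.3f}")
print("ratio p-value:", f"{report.ratio.pvalue:.3e}")
print("group mean ratios:",
      {k: round(v, 3) for k, v in report.ratio.group_means().items()})
```

prints

```
test: n=120 accuracy=1.0000 sensitivity=1.0000 specificity=1.0000 auc=1.000
ratio p-value: 2.212e-47
group mean ratios: {'mature': 1.324, 'immature': 0.524}
```

A 1,200-spectrum synthetic dataset (48 mature + 52 immature cells, 12
spectra each) is generated, normalized, split 70/20/10 at the spectrum
level, and the CNN is trained for 10 epochs: the 120 held-out spectra are
all classified correctly and the ROC is perfect. The per-cell
tryptophan/carbohydrate band ratio separates the groups decisively
(mature cells average a ~2.5× higher ratio; Welch p ≈ 2e-47). The
contribution report in `report.contribution` ranks 1623 cm⁻¹ first — on
this cleanly separable draw, occluding the tryptophan band is the only
intervention that degrades the classifier at all.

The same run from the shell, with all artifacts written to `out/`:

```bash
sersnet run --seed 1 --out out/            # default full-size generator
sersnet timecourse --seed 1 --out out_tc/  # 2/4/6 h experiment
sersnet compare --seed 1 --out out_cmp/    # CNN vs DNN vs MLP
```

## Layout

```
src/sersnet/
  synth.py        synthetic spectra, time-courses, mapping grids
  dataset.py      the SpectraDataset container
  io.py           wide/long CSV dialects + metadata sidecar, JSON/YAML
  preprocess.py   normalization, per-cell averaging, confidence bands, splits
  _nn.py          numpy layers, SGD+momentum, plateau scheduler
  model.py        architectures, training recipe, evaluation metrics
  interpret.py    band intensities, ratio marker, contributions, mapping
  pipeline.py     run orchestration, persistence, time-course, comparison
  cli.py          the `sersnet` command
docs/methods.md   model, defaults, design choices and limitations
```
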