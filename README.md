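# taafgex

Transformative adaptive activation functions (TAAFs) for landmark-to-target
gene-expression inference.

## The problem

Large expression compendia (LINCS L1000-style) measure only ~1,000 carefully
chosen *landmark* genes and computationally reconstruct the rest of the
transcriptome.  The established approach (the D-GEX family) trains deep
feed-forward regression networks from the landmark block to thousands of
*target* genes.  Because expression values span very different ranges per
gene while hidden units share one fixed sigmoidal activation, every unit
wastes capacity re-learning scale and offset through its weights.

A TAAF wraps any *inner* activation function `f` with four per-neuron
trainable parameters:

    g(f, y) = α · f(β·y + γ) + δ

`α` scales the amplitude, `β` the slope, `γ` translates the input (and plays
the role of the bias — TAAF units carry no separate bias term), and `δ`
translates the output.  At initialization `(α, β, γ, δ) = (1, 1, 0, 0)`, so a
fresh TAAF *is* its inner function, and training can deform it per neuron.
The family generalizes trainable-amplitude (`α` only) and slope-varying
(`β` only) activations, and because `tanh(u) = 2·sigmoid(2u) − 1`, a
tanh-TAAF at `(½, ½, 0, ½)` is exactly the logistic sigmoid — activation
choice becomes an initialization choice.

This package implements, in pure NumPy:

- the TAAF, its analytic partial derivatives, the 16 constrained variants,
  and the tanh↔sigmoid reparameterization (`taafgex.activations`);
- 1–3-hidden-layer networks with fixed or TAAF hidden/output layers,
  normalized initialization, 25% inverted dropout, parameter counting,
  capacity-matched width reduction, and random half-splitting of target
  genes across two networks (`taafgex.model`);
- the training protocol: mini-batch Nadam (lr 5e-4, β₁ 0.9, β₂ 0.999,
  schedule decay 0.004, batch 256), per-epoch validation MMAE, and
  best-epoch snapshot selection (`taafgex.training`);
- global (whole-matrix, not per-gene) standardization, GCT v1.2 / TSV I/O,
  and random vs series-grouped leak-free splitting (`taafgex.data_io`);
- samplewise evaluation statistics — MAE_m(s), MMAE, the pairwise MDAE /
  MMDAE, percentile-bootstrap CIs over samples, paired t and Wilcoxon
  signed-rank tests (`taafgex.evaluation`);
- per-gene expert ensembles with two-stage validation selection
  (`taafgex.ensemble`);
- differential-expression impact scoring: DE calling (pluggable backend,
  default Welch t + Benjamini-Hochberg), F_β / accuracy / MCC, candidate
  rank agreement, and repeated balanced subsampling (`taafgex.dge_impact`);
- a seeded synthetic generator emulating the landmark/target structure,
  series grouping, and planted two-class DE effects (`taafgex.synthetic`);
- a `taafgex` command-line interface wiring it all together
  (`simulate`, `split`, `train`, `evaluate`, `compare`, `ensemble`,
  `dge-eval`).

## Evaluation statistics

For model *m*, sample *s* and gene set *G*:

    MAE_m(s)  = 1/|G| Σ_g |y(g,s) − ŷ_m(g,s)|           (per-sample error)
    MMAE_m    = 1/|S| Σ_s MAE_m(s)                       (overall error)
    MDAE_{m1,m2}(s) = 1/|G| Σ_g (|y−ŷ_m1| − |y−ŷ_m2|)    (paired difference)
    MMDAE_{m1,m2}   = 1/|S| Σ_s MDAE_{m1,m2}(s)          (negative favors m1)

Samples are the independent replication unit: bootstrap CIs resample
samples, and the paired tests act on samplewise MAEs.

## Worked example

```python
import numpy as np
import taafgex as tg
from taafgex.model import ArchitectureSpec, build_network, forward
from taafgex.training import TrainingConfig, train
from taafgex.evaluation import compare_models

# simulate a landmark -> target compendium and standardize globally
ds, truth = tg.generate_expression(tg.GeneratorConfig(seed=1))
ds, scaler = tg.global_standardize(ds)
train_set, val_set, test_set = tg.random_split(ds, (0.7, 0.15, 0.15), seed=1)

config = TrainingConfig(n_epochs=60, seed=1)
preds = {}
for mode in ("fixed", "taaf"):
    spec = ArchitectureSpec(input_dim=50, output_dim=200, n_hidden_layers=1,
                            width=64, inner_kind="sigmoid", hidden_mode=mode)
    best, history = train(build_network(spec, seed=1), train_set, val_set, config)
    preds[mode] = forward(best, test_set.landmarks())
    print(f"{mode:5s} best epoch {history.best_epoch:3d}  "
          f"test MMAE {tg.mmae(tg.mae_per_sample(test_set.targets(), preds[mode])):.4f}")

report = compare_models(test_set.targets(), preds["taaf"], preds["fixed"],
                        model_1="taaf", model_2="fixed", seed=1)
print(f"MMDAE(taaf, fixed) = {report.mmdae:.4f} "
      f"[{report.ci_low:.4f}, {report.ci_high:.4f}], "
      f"Wilcoxon p = {report.wilcoxon_p:.2e}")
```

Output:

```
fixed best epoch  59  test MMAE 0.3362
taaf  best epoch  59  test MMAE 0.3190
MMDAE(taaf, fixed) = -0.0172 [-0.0176, -0.0168], Wilcoxon p = 6.11e-51
```

The TAAF network reaches a lower test error than the identically sized
fixed-sigmoid network; the MMDAE is negative (favoring the TAAF model), its
bootstrap 95% CI excludes zero, and the paired Wilcoxon test on samplewise
MAEs is decisive.

The same workflow from the shell:

```sh
taafgex simulate --out run/sim --seed 1
taafgex split --expression run/sim/expression.tsv \
    --landmark-file run/sim/landmarks.txt --out run/splits --seed 1
taafgex train --expression run/sim/expression.tsv \
    --landmark-file run/sim/landmarks.txt \
    --train-ids run/splits/train_ids.txt --val-ids run/splits/validation_ids.txt \
    --out run/taaf --hidden-mode taaf --seed 1
```

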