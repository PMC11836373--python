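# acovit

Ant-colony-optimized windowed Vision Transformer for retinal OCT B-scan
classification, with wavelet preprocessing and class-imbalance handling.

## The problem

Optical coherence tomography (OCT) produces cross-sectional B-scans of the
retina that clinicians read to diagnose choroidal neovascularization (CNV),
diabetic macular edema (DME), drusen, and healthy retinas. Automated
classification of these scans faces three recurring obstacles: multiplicative
speckle noise, severe class imbalance (rare diseases are rare in the
archive), and the cost of tuning deep models. `acovit` packages a complete,
tested treatment of this pipeline for grayscale B-scan-like imagery:

1. **Wavelet preprocessing.** Each image is decomposed by a multilevel 2-D
   DWT, `X = Σ c_{j,k} φ_{j,k} + Σ d_{j,k} ψ_{j,k}`; within each detail
   subband only the fraction *p* of coefficients with the largest magnitude
   is kept before reconstruction, suppressing speckle while preserving layer
   edges.
2. **Ant colony optimization (ACO).** A generic colony over layered discrete
   choices: candidate `c` in a layer is sampled with probability
   `τ_c^α / Σ τ^α`, trails evaporate as `τ ← (1−ρ)τ` and the best ant
   deposits `Δτ = Q/(1+F)` along its path (fitnesses are losses). The same
   engine drives augmentation-policy search
   (`F(W) = mean loss + λ·Complexity(W)`), hyperparameter tuning
   (`F(θ) = validation cross-entropy + λ·Complexity(θ)`), and wrapper
   feature selection.
3. **Imbalance mitigation.** SMOTE interpolation between same-class
   neighbours (`x_new = x_i + u·(x_nn − x_i)`, `u ~ U(0,1)`) combined with
   inverse-frequency weighted cross-entropy `w_c = N/(C·N_c)`.
4. **A modified Vision Transformer.** Multi-scale patch embeddings
   `E_{m,n} = f(X_{m,n})`, windowed self-attention restricted to a Chebyshev
   neighbourhood `N(i)` (cost `O(N·k·d)` instead of `O(N²·d)`), a learnable
   relative positional bias `P(i,j)`, and a content-aware bias `γ·g(x_j)`
   driven by per-patch pixel variance, so high-contrast patches draw
   attention. Per head:
   `logit(i,j) = q_i·k_j/√d_h + P(i−j) + γ·g_j` for `j ∈ N(i)`.

The transformer, its training loop (Adam, warmup, gradient clipping, EMA)
and the reverse-mode autodiff engine underneath are implemented in NumPy —
no deep-learning framework is required.

A synthetic-data module generates OCT-like fixtures — warped retinal layer
stacks with class-specific lesions and multiplicative speckle, imbalanced
37,206 : 11,349 : 8,617 : 26,323 like the public Kermany benchmark — so the
entire pipeline is exercisable and testable without any external download.

## Worked example

```python
import numpy as np
from acovit import RunConfig, run_pipeline
from acovit.synthetic import SyntheticSpec
from acovit.vit import ModelConfig

cfg = RunConfig(
    synthetic=SyntheticSpec(counts=(120, 40, 30, 90), seed=0),
    model=ModelConfig(scales=(8, 16), d=32, heads=4, blocks=2,
                      window_radius=1, dense_neurons=64, seed=0),
    imbalance_mode="smote+weighted",
    epochs=10,
    seed=0,
)
result = run_pipeline(cfg)
print({k: round(v, 3) for k, v in result.report.to_dict().items()
       if isinstance(v, float)})
```

This generates 280 synthetic B-scans at the 12:4:3:9 class ratio,
wavelet-denoises them, oversamples the minority classes to balance, trains
the tiny transformer for 10 epochs and prints the held-out metrics:

```
{'accuracy': 0.893, 'precision_macro': 0.897, 'recall_macro': 0.851,
 'f1_macro': 0.863, 'minority_class_accuracy': 0.667,
 'recall_class_0': 0.917, 'recall_class_1': 0.875,
 'recall_class_2': 0.667, 'recall_class_3': 0.944}
```

`minority_class_accuracy` is the recall of the smallest-support class
(drusen here); running the same seed with `imbalance_mode="none"` drops it
to 0.0 while overall accuracy stays deceptively high — the pattern the
SMOTE + weighted-loss combination exists to fix.

The same pipeline is scriptable from the shell:

```bash
acovit generate --out data/ --counts 120,40,30,90 --seed 0
acovit train --data data/ --mode smote+weighted --epochs 10 --out runs/demo
acovit report --run runs/demo
```

## Layout

| module | contents |
| --- | --- |
| `acovit.aco` | generic ant colony optimizer (trails, sampling, deposits) |
| `acovit.dwt` | multilevel DWT, coefficient retention, reconstruction |
| `acovit.augment` | augmentation operators + ACO policy search |
| `acovit.imbalance` | SMOTE and weighted cross-entropy |
| `acovit.vit` | multi-scale windowed-attention transformer |
| `acovit.autodiff` | the reverse-mode engine the model trains on |
| `acovit.tuning` | hyperparameter tuning + wrapper feature selection |
| `acovit.metrics`, `acovit.pipeline`, `acovit.cli` | metrics, orchestration, CLI |
| `acovit.synthetic` | OCT-like fixtures, toy landscapes, feature matrices |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
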