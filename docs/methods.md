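# Methods

This note records the models and procedures `acovit` implements, the
defaults it ships, the choices made where the design was genuinely open,
and what the synthetic fixtures do and do not establish.

## Ant colony optimizer

The optimizer works on a layered graph: each layer is one discrete decision
(a hyperparameter, one augmentation operator, one feature's include/exclude
bit) with finitely many candidates. Pheromone lives on candidate *nodes*
rather than edges, which keeps the dynamics invariant to layer order and
matches the way a per-hyperparameter desirability is usually described.
There is no separate heuristic-desirability term; selection probabilities
are `τ^α` normalized within the layer.

Per iteration, `n_ants` solutions are sampled, evaluated, and the
iteration-best deposits `Δτ = Q/(1+F)` along its path after global
evaporation `τ ← (1−ρ)τ`; with the elitist flag (on by default) the
global-best path receives the same deposit. Fitnesses are losses
(minimization); maximizers must negate. `+inf` is accepted as a sentinel
for infeasible solutions (the empty feature subset) and deposits nothing.

Defaults: `n_ants=10`, `ρ=0.3`, `Q=1`, `α=1`, `τ0=1`, `max_iterations=50`,
`patience=10`. The trail floor is `τ_min=0.05` — 5 % of `τ0`, in the spirit
of max–min ant systems. A much smaller floor (say `1e-6`) lets trails
collapse after a handful of iterations and the colony locks into whatever
the first few deposits favoured; on enumerable test landscapes that cost
roughly 15 % of runs the true optimum. The 5 % floor keeps a small
exploration probability alive per layer while still allowing >95 % of the
selection mass to concentrate, and together with elitist deposits it makes
convergence both fast (last best-so-far improvement typically within 20–40
iterations on a 625-configuration landscape) and reliable across seeds.

## Wavelet preprocessing

Multilevel separable 2-D DWT (PyWavelets), default `haar` at 2 levels with
symmetric boundary extension. "Significant" coefficients are the largest by
absolute magnitude, ranked *within each detail subband independently*, so
coarse structure never competes with fine detail for the retention budget;
the approximation band is never thresholded. The retention parameter is a
fraction `p ∈ [0,1]` (default 0.5) rather than an absolute threshold, so it
is scale-free. Ties at the cutoff keep the lower row-major index.

Orthogonal wavelets give perfect reconstruction (`< 1e-8` max error at
`p=1`). Energy conservation (Parseval) additionally requires the transform
to be non-redundant: with symmetric extension that holds exactly for Haar
on even-sized images (the default configuration); longer filters pad the
subbands and conserve energy only approximately. Tests pin the default
wavelet for the energy property.

## Synthetic OCT-like data

The generator emulates the gross geometry of a retinal B-scan: 4–6 smooth
horizontal bands of graded intensity between 18 % and 80 % of image height,
warped by a low-amplitude sinusoid, with the inner limiting membrane and
RPE bands brightest. Class overlays: CNV adds one bright ellipse below the
band stack; DME subtracts 2–4 dark circular pockets inside the bands;
drusen adds 4–9 small bright bumps along a deep band boundary; Normal adds
nothing. Speckle is multiplicative, `pixel ← pixel·(1+σ_s z)` with
`σ_s = 0.05` by default, as appropriate for coherent imaging. All base
randomness is drawn before overlay randomness, so images of different
classes generated from the same generator state share an identical band
template — lesion-polarity assertions in the tests are exact.

Lesion extents and amplitudes (default 0.2–0.4 intensity) were chosen once
so that the four classes are separable by construction: a plain logistic
regression on raw pixels reaches ≥ 0.9 validation accuracy on a 280-image
draw. Class-count defaults mirror the public benchmark proportions
37,206 : 11,349 : 8,617 : 26,323 (CNV : DME : drusen : Normal), scaled by
largest-remainder rounding.

What passing tests on these fixtures shows: the pipeline's machinery —
denoising, resampling, optimization, attention, training — behaves as
specified under controlled, separable, honestly imbalanced conditions. What
it does not show: performance on real OCT scans, whose speckle statistics,
anatomy and label noise are far richer. No claim about real-data accuracy
is made or tested.

## Transformer

Tokens are flattened square patches at each configured scale (default
scales 8 and 16 px), linearly projected to `d`, plus a learned per-scale
embedding and a learned absolute position embedding per grid cell. Inside
attention, position enters only through the relative bias `P(Δrow, Δcol)`,
a per-head learnable table over clipped offsets (`|Δ| ≤ r`), initialized to
zero so the dense-attention equivalence holds exactly at initialization.
Content-aware weighting adds `γ·g_j` to every logit column, where `g_j` is
the patch's pixel variance min-max normalized over the image (constant
patches score 0) and `γ` is a learnable scalar, initialized to 0.25 — small
enough that early training is not steered by speckle-driven variance, large
enough that the term is alive. Scales do not attend to each other; each
scale's token grid runs through the shared encoder blocks and the pooled
per-scale summaries are concatenated before the dense head (mean pooling,
no class token). Blocks are pre-norm with a 2× GELU MLP; a final layer norm
precedes pooling.

Attention is restricted to the Chebyshev ball `N(i)` of radius `r`
(self-inclusive, default 1); out-of-window logits are −∞, so each softmax
row sums to 1 over `N(i)` and the pair count is `Σ|N(i)| ≤ N(2r+1)²`,
linear in `N` at fixed `r`.

### Autodiff and training

The model runs on a small reverse-mode engine over NumPy arrays (float32
by default for the model; float64 wherever oracle comparisons or
finite-difference checks need it). Attention's two big contractions are
single fused `einsum` ops with `einsum` backward passes, which matters
because at desk scale the binding resource is memory traffic, not FLOPs.
Gradients are verified against central finite differences in the tests.

Training is Adam (β = 0.9/0.999) with linear warmup over the first 10 % of
steps then a constant learning rate (default 1e-2; cosine decay is
available but off — with only a few hundred steps the decay starves late
learning), global gradient-norm clipping at 1.0, label smoothing 0.1, batch
size 8, and an exponential moving average of the weights (decay 0.99 with
the usual `(1+t)/(10+t)` warmup) that becomes the final model. Each of
these is standard practice; together they make 10-epoch desk-scale runs
reproducible and stable where raw Adam at this step budget is noisy.

## Imbalance handling

SMOTE draws a minority sample `x_i`, one of its `k=5` nearest same-class
neighbours `x_nn` (Euclidean distance on flattened copies, bicubically
downsampled to 64×64 when larger, for speed), and interpolates at full
resolution: `x_new = x_i + u(x_nn − x_i)`, `u ~ U(0,1)`. Synthetic samples
are therefore exact convex combinations of two originals and inherit the
[0,1] range; they are flagged, and flagged filenames survive a round-trip
to disk. Targets default to the majority count.

Weighted cross-entropy uses `w_c = N/(C·N_c)`; in the hybrid
SMOTE + weighted mode the weights are recomputed *after* resampling (hence
all ones when fully balanced) — a flag restores weights from the original
counts for users who want double emphasis.

## ACO applications

*Hyperparameter tuning* searches the grid {learning rate 0.1/0.01/0.001/
0.0001} × {batch 16/32/64} × {dense width 128/256/512/1024} with fitness
`validation cross-entropy + λ·(width / max width)`, λ default 0.1 — the
dense width is the only capacity axis in the space, so it is the whole
complexity term. Candidate configurations train for a fixed small epoch
budget (default 3) so comparisons across ants are fair.

*Feature selection* gives every feature an include/exclude layer and scores
subsets by the validation log-loss of an L2-regularized linear softmax on a
fixed stratified 70/30 split plus `λ·|S|/p`. A linear probe keeps wrapper
search affordable; the deep model is deliberately not in the loop. The
empty subset scores +inf, so the returned mask is never empty.

## Metrics and pipeline

Row-true/column-predicted confusion matrices; per-class precision/recall
with the 0/0 → 0 convention; macro averages are unweighted class means;
minority-class accuracy is the recall of the smallest-support class, ties
to the lowest index, with the minority identified from the *original*
(pre-resampling) supports. The pipeline is stratified-split (default 80/20,
seeded), stages run in the order: load/generate → DWT → optional policy
search → resampling/weights → optional hyperparameter search → training →
evaluation, every stage seeded from one master seed via `SeedSequence`, and
artifacts (metrics CSV/YAML, traces, checkpoint, config snapshot) are
written so any stage can be re-run from its predecessor's output. Early
stopping is off by default so imbalance modes are compared on an equal
epoch budget.

## Problem sizes used in tests

The shipped tests run the full pipeline at 64×64 resolution with a
2-block, d=32 transformer on a few hundred images, the optimizer studies on
enumerable toy landscapes (≤ 625 configurations), and feature selection at
n=200, p=50. These sizes are the package's chosen desk-scale operating
points: large enough that every mechanism is exercised end to end, small
enough that the whole suite runs on one CPU in minutes.

## Known limitations

- The generator does not model A-scan physics (shadowing, attenuation,
  motion artifacts); conclusions about real OCT transfer are out of scope.
- SMOTE in pixel space can blur structural lesions (an interpolated drusen
  image has fainter bumps than either parent); the directional benefit on
  minority recall survives this, but pixel-space interpolation is a known
  weak point for structured imagery.
- The ACO engine is single-objective and sequential; parallel ant
  evaluation and continuous-domain variants are non-goals.
- Windowed attention uses a fixed (non-shifted) window per block; tokens
  interact across windows only through depth.
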