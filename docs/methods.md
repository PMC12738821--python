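# Methods

## Scope and design

`leafvit` implements a six-layer Vision-Transformer classifier for
four-class leaf-disease images, in which dense self-attention can be
replaced layer-by-layer with bi-level routing sparse attention and the
linear classification head with a B-spline Kolmogorov–Arnold (KAN) stage.
The entire network — forward passes, analytic backward passes, Adam/Adagrad
— is written in numpy. This is deliberate: at desk scale (64×64 images,
d = 64, ~0.3 M parameters) a framework-free implementation is fast enough
on one CPU, is bit-reproducible from a single seed, and lets every
component be checked against straight-line oracles without autodiff
machinery in the way.

## Encoder

* **Patch embedding.** Raster-ordered p×p patches (row-major, top-left
  origin), flattened channel-last, projected by E ∈ ℝ^(p²C×d); a learned
  CLS token occupies row 0; learned position encodings are added. All
  weights initialise from a seeded normal(0, 0.02).
* **Attention.** Per-head scaled dot-product softmax(QKᵀ/√d_k)V. The
  formulation defines a single head; we concatenate h heads and apply a
  learned output projection W_o (identity-initialisable in tests), the
  standard way to return to width d.
* **MLP.** GELU(xW₁+b₁)W₂+b₂ with expansion ratio 4 and the *exact*
  erf-based GELU (the tanh approximation would poison 1e-5-level oracle
  comparisons). The source formulation prints "+W₂", which is
  shape-inconsistent; the matrix product is the only consistent reading and
  is what we implement.
* **Residual wiring.** Post-norm, exactly as printed: LayerNorm *after*
  each residual add. Standard ViT is pre-norm; we keep the printed order
  and accept the (desk-scale-irrelevant) optimisation differences.
* **DropPath.** The whole sublayer output is dropped per sample with
  probability p (default 0.1, constant across layers — the rate is not
  stated) and rescaled by 1/(1−p) when kept; identity at inference.
* **Head.** y = softmax(head(LayerNorm(X₀^L))); dropout 0.5 on the head
  input during training. No extra final-encoder LayerNorm is inserted —
  only what the readout formula states.

## Routed attention

The patch-token grid (8×8 in the test preset) is cut into S×S regions
(default S = 4, so 2×2-token regions; S is not stated by the source and is
configurable). Region-level queries/keys are the *means of the projected*
per-head Q/K (projection before summarisation, matching the printed
order). The adjacency A_r = Q_r K_rᵀ is pruned row-wise to its k largest
entries (default k = 4), ties broken toward the lower region index so the
routing index is platform-independent. Routing is per-head by default;
`share_routing` averages A_r over heads. Token-level attention then runs
over the gathered keys/values of the routed regions, and a per-channel
(depthwise) 5×5 zero-padded convolution of the value grid — the local
context enhancement, zero-initialised — is added.

Two choices were genuinely open:

* **CLS.** The routing equations live on a 2-D grid, but the classifier
  carries a CLS token. The CLS token attends densely over the whole
  sequence, and its key/value is appended to every region's gathered set.
  With k = S² and a zero LCE kernel the routed layer is then *exactly* the
  dense layer (machine-precision agreement), which is the invariant all
  equivalence oracles rely on; with k < S² each patch token keeps one
  global summary route, a standard global-token pattern.
* **Kernel size / sharing.** The source says only "deep convolution"; 5×5
  per value channel was chosen and is configurable (`lce_kernel`).

## KAN head

Each (class, input) pair carries one univariate function
f(x) = Σ_{k=1..K} c_k B_k(x; t), K = 5 cubic B-spline bases on clamped
uniform knots shared per layer (the one sharing scheme consistent with
per-function coefficients). The head input is already LayerNorm-ed, so
knots span [−3, 3] (≈99.7% coverage); inputs are clamped to the domain,
making the functions constant (zero-gradient) outside. Basis evaluation is
an in-package vectorised Cox–de Boor recursion (cross-checked in tests
against an independent textbook recursion and `scipy.interpolate.BSpline`);
derivatives use the knot-difference operator.

The curvature penalty λ Σ ∫(f″)² dx (λ = 0.1) is computed exactly: the
second-derivative operator maps coefficients to a degree-(p−2) spline, and
per-interval Gauss–Legendre quadrature of order degree+1 integrates the
piecewise-polynomial Gram matrix exactly, so the penalty is a quadratic
form c^T G c with closed-form gradient 2λGc. The width-adaptation rule
m_new = ⌊m_init‖∇‖/α⌋ (α = 1) is exposed as `adapt_width`, a
*between-trainings diagnostic only*: no schedule is stated, and resizing
mid-training would make checkpoints ill-defined. Whether the KAN also
replaces the in-layer MLP is ambiguous in the source; the head-replacement
reading is implemented (deeper KAN stacks are supported as `KANNetwork`
but are not the default).

## Synthetic data

The generator states a world matching the four phenotypes: an elliptical
green leaf on a noisy soil-toned background, with (a) 2–6 elongated (axis
ratio ≥ 2.5) brown lesions in the interior, (b) chlorotic yellowing
confined to a ~10%-width boundary band, (c) an unblemished lamina, and (d)
wilt discoloration covering 65–85% of the leaf. Colours and geometry
jitter per image; every image is a pure function of (class, spec, seed)
and ships with its ground-truth lesion mask. Classical augmentation
(rotation, 0.8–1.2 scaling, flips) is deterministic given its parameters;
right-angle rotations take an exact `rot90` path so four quarter-turns are
the identity. Dataset construction takes explicit per-class totals (the
published per-class augmented-to-original ratios are mutually
inconsistent, so no ratio is inferred) and generates ~40% base images plus
augmented copies, logging the realised proportions.

What a green test does and does not establish: the classes are separable
by global colour statistics (a 3-bin HSV histogram nearest-centroid
classifier exceeds 90% leave-one-out accuracy — a standing regression
test), so the end-to-end criterion shows the architecture can *learn* an
easy four-class image task under the stated training preset. It does not
emulate field conditions — occlusion, illumination domains, background
clutter, co-infection — and says nothing about the headline accuracy on
the private field dataset, which is not reproducible.

## Splits, training, evaluation

The 3:1:1 split is per-class (stratified): val = test = ⌊n/5⌋, train the
remainder — the one rounding rule that reproduces the published split
table exactly from the published class totals. Training uses the sweep-
winning preset (Adam, lr 1e-4, 100 epochs, batch 64) with L2 weight decay
(coefficient unstated; default 1e-4, applied to weight matrices, not to
biases/LayerNorm/CLS/position parameters), the KAN curvature penalty, and
early stopping on validation loss (patience unstated; default 10) with
best-validation weights restored. Batch normalisation is *not* inserted:
its placement is unstated and it would conflict with the encoder's
LayerNorm. Inputs are normalised from [0,1] to [−1,1] (standard ViT
preprocessing; raw [0,1] inputs converge visibly slower at lr 1e-4).

Evaluation builds the 4×4 confusion matrix (rows = truth) and reports
per-class one-vs-rest precision, recall, specificity, F1 and accuracy —
"accuracy" per class is the one-vs-rest binary accuracy, the only reading
under which it can differ across classes — plus overall accuracy
(trace/total) and one-vs-rest ROC/AUC from softmax probabilities. A class
absent from the test set reports `None` for undefined metrics, never 0.
Five-fold cross-validation is stratified (scikit-learn `StratifiedKFold`)
with per-fold seeds.

## Numerical choices

* Default dtype is float64; the training path can run the encoder body in
  float32 (the head and spline machinery stay float64), about 2× faster on
  one CPU. Constants are Python floats throughout so float32 arrays are
  never silently promoted.
* All randomness flows from one master seed through named substreams
  (CRC32 of the stream name into a `SeedSequence`), so data generation,
  initialisation, shuffling and DropPath/dropout are independently
  reproducible; reruns produce bit-identical loss traces.
* Top-k ties: stable argsort on negated scores → lower index wins,
  identical across platforms.
* Non-finite losses raise a `DivergenceError` carrying the last finite
  weights.
* Profiling counts multiply-accumulates as 2 FLOPs over matrix products,
  attention contractions and the depthwise convolution only; it reports
  whatever geometry it is given and makes no claim of matching any
  published parameter/FLOP table (the hyperparameters needed to do so are
  not printed; the 224×224/d=768 profiling preset is this package's
  choice of a standard ViT-Base geometry).

## Known limitations

* Desk scale only: no GPU kernels; the sparse attention is implemented for
  correctness, and its complexity advantage shows up in operation counts,
  not wall-clock at an 8×8 grid.
* The generator's phenotypes are colour/geometry caricatures; models
  trained on them do not transfer to photographs.
* Routing indices are recomputed per forward pass and treated as
  non-differentiable (gradients flow through gathered K/V and the queries,
  not through the top-k selection) — the standard hard-routing treatment.
* Whether the desk-scale routed model beats its dense counterpart is
  recorded in training histories but never asserted: at this scale that
  ordering is not a testable claim.
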