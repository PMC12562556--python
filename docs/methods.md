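# Methods

`wavedetr` implements a compact, NMS-free, query-based real-time detector for
grading *Stropharia rugoso-annulata* mushrooms from RGB images, built around
two components: a wavelet-based **Low-Frequency Feature Integrator (LFFI)**
in the backbone and **Token Statistics Self-Attention (TSSA)** at the deepest
feature scale. Everything runs on CPU: the neural-network layers are built on
a small reverse-mode autodiff engine over numpy (`wavedetr.nn`) written for
this package.

## The grading problem

Specimens are graded First/Second/Third from two morphological ratios:
**RDHP** (cap diameter / cap height) and **RLDS** (stalk length / stalk
diameter). The rule table is: First — RDHP 1.5–2.5, RLDS 0–1.5; Second —
RDHP 1.0–1.5, RLDS 1.5–2.5; Third — RDHP 0–1.0, RLDS > 2.5, with **RLDS
prevailing whenever the two ratios disagree**. We treat the intervals as
half-open `[lo, hi)` with the last RLDS interval unbounded; the table prints
no endpoint rule, so the convention is ours. Because the three RLDS intervals
then partition (0, ∞) and RLDS wins every conflict, the assigned grade always
equals the RLDS-implied grade; `assign_grade` still evaluates both ratios so
the conflict logic is explicit and testable.

## Wavelet transform (`wavedetr.wavelet`)

A separable filter-bank DWT with periodic boundary handling and orthonormal
filters (Haar default, `h = [1/√2, 1/√2]`; other orthonormal families pulled
from PyWavelets coefficients but filtered through this module's own
analysis/synthesis so conventions are fixed). The high-pass filter is derived
from the quadrature-mirror relation `g(k) = (−1)^k h(1−k)`, re-anchored onto
the support `0..L−1` by an even shift, i.e. the alternating flip
`g[k] = (−1)^k h[L−1−k]`.

Conventions that matter (libraries disagree, so they are pinned and tested):

* **Sub-band naming** — `lh` (horizontal detail) = rows low-passed (filtering
  along axis 1), columns high-passed (axis 0); `hl` is the converse. This
  matches PyWavelets' `(cH, cV)` order and the usual "LH captures horizontal
  edges" reading.
* **Scaling** — orthonormal (1/√2) filters, so one decomposition level maps a
  constant field `c` to an LL value of `2c`, and the four sub-bands conserve
  energy exactly. Perfect reconstruction holds to < 1e−10 for even
  dimensions; odd dimensions are reflect-padded first.
* Multi-channel / batched arrays are decomposed depthwise along the last two
  axes (`ll_downsample`), whose adjoint (synthesis with zeroed detail bands)
  is the backward pass of the corresponding autodiff op.

## LFFI (`wavedetr.lffi`)

Repeated strided convolution suppresses the low-frequency content that
carries the overall shape of large targets. Each LFFI unit n receives three
inputs: the backbone's main feature map at that scale, the **approximate
image** `b_n` (the n-th LL of the input image — a low-pass image pyramid),
and the **memory feature** `a_n` (the LL of the previous unit's fused
output, initialized `a_0 = b_0`). Both auxiliary inputs pass through 1×1
convolutions + GroupNorm to match the main map's channels, are added
element-wise, and the fused map's LL becomes `a_{n+1}` at half resolution.
Only LL is kept; the three detail bands are discarded by design.

Decisions where the published description leaves gaps:

* `b_0` is the input image pooled by iterated LL extraction down to the
  first injection resolution (stride 8), since the raw image cannot match
  feature-map dims.
* One unit per consumed scale — three injections at strides 8/16/32.
* Projections are **zero-initialized**, so a freshly built model is exactly
  the plain backbone; training opens the wavelet branch gradually.
  `proj_a`/`proj_b` do not share weights.
* The wavelet on feature maps is depthwise orthonormal Haar, not learned.

## TSSA (`wavedetr.tssa`)

Instead of pairwise token similarities, attention is derived from the
maximal-coding-rate-reduction (MCR²) objective ΔR = R − R_c, where
`R(Z) = ½ logdet(I + (d/ε²) ZZᵀ/n)` measures the coding volume of all
tokens and `R_c` the membership-weighted per-group volumes. A variational
upper bound replaces each group's logdet with a sum of a concave function
`f` over the **diagonal** of the projected second-moment matrix — O(n·d·p)
instead of O(n·d²+d³). Gradient descent on that bound yields the token
update

    z_j⁺ = z_j − (τ/n) Σ_k Π_jk U_k D(Z, π_k | U_k) U_kᵀ z_j,

with `D = diag(f′(m_i))` and `m_i` the π-weighted second moment of projected
coordinate i. We take `f(x) = log(1 + (d/ε²)x)`, which makes the bound tight
at each group's eigenbasis; the exact functional form of `D` follows from
that choice and is pinned by a brute-force loop oracle in the tests.
Memberships `Π` are row-softmaxes of negative per-group projected energies
with a learnable temperature (the objective does not pin down a membership
head; this choice is configurable). `τ` is a learnable positive scalar
(`exp` parameterization, init 1). `ε` defaults to 0.5. Projections default
to rank `p = d/K` per group — full-rank orthogonal projections would give
every group identical energies and collapse the memberships. Orthogonality
of each `U_k` is maintained by projecting the parameter back onto the
Stiefel manifold (QR) after each optimizer step, avoiding differentiation
through QR; a config flag can disable enforcement.

Key testable properties: `R_c` at K=1 equals `R`; exact rates match dense
eigendecompositions; the variational bound dominates the exact rate for any
orthogonal projection (Schur-Horn majorization + Schur-concavity) with
equality at the eigenbasis; the vectorized update equals the explicit
per-token/per-group loop; operation counts are affine in the token count
(ratio ops(2n)/ops(n) ≈ 2), against the quadratic softmax-attention
reference exported as `naive_softmax_attention`.

## Detector (`wavedetr.detector`)

An 18-layer-style residual backbone (widths configurable; the desk-scale
default uses widths 16/32/48/64 with one block per stage) feeds S3/S4/S5
with LFFI injections. At S5, an encoder block applies TSSA (or standard
multi-head attention, for ablations) plus a feed-forward layer; 2-D
sinusoidal positional encodings are added before it (flag-controlled — the
replaced block traditionally uses them). A light top-down pathway (1×1
lateral + ×2 nearest upsample + add, 3×3 smoothing) fuses the three scales.

The decoder is a deliberately **minimal set-prediction stand-in** for the
original deformable-attention decoder, which the two contributions do not
depend on: `decoder_layers` × [query self-attention, cross-attention to the
fused multi-scale tokens, FFN]. The learned query embedding is added to
attention queries/keys (not values) at every layer so the 30 query slots
stay distinguishable, and each query carries a reference box (logit-space)
from which the box head predicts offsets — both standard stabilizers for
query-based detectors at small scale. Which pyramid levels the decoder
reads is configurable (`decoder_scales`); the toy configuration uses
P4+P5, since the targets are large. Class and box heads are shared across
layers; every decoder layer is supervised (auxiliary losses).

Following the common encoder-proposal scheme of this detector family, a
dense per-token head on the fused tokens predicts a (class, box) proposal
anchored at each token's cell (`encoder_proposals`, on by default). It is
trained with the same Hungarian-matched loss as the decoder layers, and the
top-k proposals by class score seed the decoder queries' reference boxes
(detached; plain top-k — no IoU-aware selection). This densifies the
supervision reaching the backbone and starts the queries near plausible
objects, which is what makes from-scratch CPU training converge in minutes;
disabling the flag falls back to static grid-initialized references.

Training uses one-to-one Hungarian matching (SciPy's assignment solver) on
a weighted cost of class probability, L1 in normalized cxcywh space, and
GIoU, with default loss weights (2, 5, 2) and a no-object class weighted
0.1 in the cross-entropy; a sigmoid focal-loss variant (`class_loss:
"focal"`) is available. Because matching is one-to-one, inference is
NMS-free: `predict` thresholds query scores (default 0.3) and returns boxes
directly. Optimization is Adam with global-norm gradient clipping and a
×0.1 step decay over the last quarter of the epochs. The training loop can
apply the study's stated augmentation suite on the fly (rotation ±15°,
scale 0.9–1.1, brightness ±20%, Gaussian noise σ ∈ [0, 0.01], horizontal
flip p = 0.5), with boxes transformed through the axis-aligned hull of
rotated corners.

`count_params_flops` profiles architectures analytically: parameters from
the constructed graph, multiply-accumulate counts from closed-form per-layer
formulas (conv: `2k²·C_in·C_out·H_out·W_out`; TSSA linear in n; naive
attention quadratic). Counts are independent of batch size and seed.

## Synthetic scenes (`wavedetr.synthgen`)

No public dataset exists, so every end-to-end test runs on a deterministic
scene generator that reproduces the study's *geometry*, not its visual
appearance: 4:3 frames (default 320×240; the camera's 1280×960 via config),
1–3 mushrooms per scene, grade mix 33.8/37.1/29.1 mirroring the study's
class balance, targets covering ≈20–60% of the frame (the "large target"
regime). A mushroom is a filled ellipse cap over an oriented rectangular
stalk hanging from the cap's lower edge; the ground-truth box is the
analytic hull of both primitives. Specimen dimensions are sampled so RDHP
and RLDS land strictly inside the requested grade's ranges with ≥5% margin
from every boundary — `assign_grade` recovers the requested grade by
construction (no label noise unless switched on). Specimens are sized by
target hull area and rescaled uniformly if a tall Third-grade hull would
not fit the frame (ratios are scale-invariant, so grades are unaffected).
Background is bilinear low-frequency color noise plus Gaussian pixel noise.
All outputs are pure functions of (config, seed).

What passing tests on these scenes do **not** show: robustness to real
texture, lighting, occlusion, soil clutter, or seasonal appearance — the
generator has none of these. They do show that the assembled
LFFI+TSSA+set-prediction pipeline can learn localization and ratio-based
grade classification end to end, and that every bookkeeping step (splits,
formats, metrics) behaves exactly as specified.

## Problem sizes and budgets

The toy end-to-end demonstration trains on 200 scenes at 320×240 (seed 7),
resized to a 96×128 model input, with the toy widths, 3 decoder layers and
30 queries — sizes chosen so a full run (training + evaluation) completes
in minutes on one CPU core. The wavelet/TSSA property suites use ≤ 8×32
token matrices and ≤ 64×64 images, where dense eigendecomposition oracles
are exact and fast.

## Known limitations

* The autodiff engine is float32 and single-threaded numpy; it is a correct
  but not fast substrate, so the backbone is far smaller than the
  published architecture and accuracy numbers are not comparable to the
  study's full-scale results.
* The decoder stand-in omits deformable attention and IoU-aware query
  selection; it preserves the NMS-free query-based contract only.
* The grading rules are exercised on synthetic geometry; real annotation
  noise (ambiguous specimens near rule boundaries) is not modelled.
* TN counts are meaningful only as the background cell of the confusion
  matrix; open-set detection has no TN otherwise.
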