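# Methods

## Problem and data model

Brown core is an internal physiological disorder of pear fruit: the core
browns first, so early grades (1–3 of a 0–5 scale, 0 = healthy) are
invisible from the outside and conventionally require cutting the fruit
open. A metal-oxide-semiconductor (MOS) electronic nose offers a
non-destructive alternative: ten gas sensors with different volatile
sensitivities sample the fruit's headspace, and the joint response forms
an odour fingerprint that a classifier maps to a browning grade.

Each measurement is the conductivity ratio G/G0 (sample gas over
carbon-filtered air) of each of the 10 sensors at 1 Hz over a 90 s
collection stage. The curve rises quickly and plateaus by about 30 s, so
the plateau readings — the *stable values* (SV), seconds 31–90 inclusive —
are used directly as features: **each retained second is one 10-dimensional
feature row**, with no per-fruit aggregation. A cohort of 240 fruit thus
yields a 240 × 60 = 14,400-row training matrix and 102 fruit a 6,120-row
test matrix. Time is 1-based in seconds and the window is inclusive on
both ends (60 rows per fruit — forced by the matrix arithmetic above).
No feature scaling is applied by default; an optional standardisation flag
exists but is off, since raw stable values are what the classifiers see.

Evaluation granularity is likewise per feature row (60 rows per fruit);
per-fruit aggregation (e.g. majority voting) is deliberately not the
default so that reported accuracies stay commensurate with the row-level
matrix arithmetic.

## Synthetic cohorts

The real pear dataset is not publicly deposited, so the package ships a
generator that emulates the qualitative structure of MOS responses:

    ratio(t, s) = 1 + A[c, s] · (1 − exp(−t/τ)) + ε,   ε ~ N(0, noise_sd²)

truncated below at a small positive floor (conductivity ratios are
positive). Defaults:

* **τ = 5 s** — puts the curve within 1% of its plateau by 25 s,
  matching the observed "stable by 30 s" behaviour (any τ ≤ 10 satisfies
  the plateau-by-30 s property the tests assert).
* **noise_sd = 0.02** — roughly 1–2% of the plateau amplitudes, a
  realistic repeatability figure for MOS arrays under controlled
  temperature and humidity.
* **cohort sizes** — the study's per-grade fruit counts: (9, 21, 42, 77,
  49, 42) training, (3, 8, 15, 38, 20, 18) test. The strong class
  imbalance is the point: it is what SMOTE balancing has to fix.
* **grade profiles** `A[c, s]` — a per-sensor baseline (sensor 4,
  hydrogen, dominant — mirroring the dominant PC1 loading this channel
  shows on real pears) times `clip(1 + separability · (trend + jitter),
  0.05, ∞)`, where `trend` grows linearly with grade (browner cores emit
  more volatiles overall) and `jitter` is fixed N(0, 0.12) noise drawn
  once from a frozen seed. The profiles are part of the simulated world:
  cohorts with different seeds sample different fruit from the *same*
  six grade distributions.
* **separability** scales grade distinctness: 0 collapses all grades onto
  one distribution (the null case for calibration); 1.0 (default) gives a
  clean, well-separated cohort used for label-recovery checks; 0.5 is the
  reduced-separation condition used for the model-ranking comparison.

What the generator does **not** emulate: sensor drift and ageing,
humidity/temperature interference, cross-fruit headspace carry-over,
within-fruit response correlation beyond the shared profile, and any
chemically meaningful VOC composition. Passing tests therefore demonstrate
that the pipeline's arithmetic, optimisation and analytic solutions are
correct and that the classifiers can recover class structure of this
saturating-curve family — not that real-pear accuracies would be
reproduced.

## SMOTE balancing

Synthetic minority rows are drawn on segments between a minority row and
one of its k nearest minority neighbours, `x_m + α (x_n − x_m)`,
α ~ U(0, 1). The printed form of this update in some descriptions flips
the difference (`x_m + α (x_m − x_n)`, an extrapolation *away* from the
neighbour); the package defaults to standard interpolation and offers the
flipped variant as `mode="paper-sign"` for comparison. k defaults to 5
and is reduced per class to M − 1 when a class has only 2 ≤ M ≤ k rows;
a class with fewer than 2 rows cannot be interpolated and raises.

Every grade is raised to the majority-grade count (4,620 training rows
per grade → 27,720 total; 2,280 test rows per grade → 13,680 total for
the study cohorts). Balancing is applied independently to the training
and test tables because that is the protocol being reproduced; inflating
a *test* set with interpolated rows changes what the evaluation measures,
so downstream reporting keeps both the balanced-test and original-test
paths and the pipeline evaluates both.

## Optimiser

All gradient-trained layers use the package's own Adam: moving averages
of the gradient and squared gradient with bias correction and the
canonical `√v̂` in the step denominator (the square root is occasionally
dropped in transcriptions; without it the step is dimensionally
inconsistent with the algorithm being cited). Defaults β₁ = 0.9,
β₂ = 0.999, lr = 10⁻³, ϵ = 10⁻⁸. Two closed forms anchor the tests: zero
gradient at zero moments is a fixed point, and a constant gradient g
telescopes to exactly m̂ = g, v̂ = g², hence steps of −lr·g/(|g| + ϵ).

## Classifiers

All four share the loss `−mean_i Σ_c l_ic log y_ic + α_r Σ ‖W‖²` with
α_r = 10⁻⁴ by default (the regularisation strength was not published;
10⁻⁴ is a conventional weak penalty) and one-hot targets; `argmax` ties
break toward the lowest grade.

* **BPNN** — hidden widths (21, 43, 87), ReLU, softmax output; the
  published comparator architecture.
* **ELM** — 500 random sigmoid hidden units, U(−1, 1) weights and biases,
  output weights `β = pinv(H) T`. The pseudoinverse is used because H is
  non-square in general; an optional ridge solve `(HᵀH + λI)⁻¹HᵀT`
  guards conditioning (λ = 0 by default).
* **RBFNN** — centres by k-means (k = 3 by default, chosen on the study's
  data by the SSE elbow; `rbf_select_k` exposes the SSE curve and picks
  the k with the largest relative drop SSE(k−1)/SSE(k)). Shared width
  from the maximum centre distance μ_max: the classical heuristic
  μ_max/√(2k) by default, with `width_mode="paper"` giving the literal
  μ_max/k. With k = 1, μ_max is undefined and an explicit width is
  required. Output layer = linear + softmax trained by Adam (a
  least-squares variant is available).
* **BP-ELM hybrid** — Step 1: two ReLU layers (defaults 43 and 87 units,
  mirroring the BPNN's upper layers; the published hybrid widths are not
  stated) are trained by Adam *through a temporary softmax head*, since
  the backprop stage needs a differentiable objective before the analytic
  head exists; the alternative of backpropagating through the frozen
  random layer is available as `pretrain_mode="through-frozen"`.
  Step 2: the head is discarded and a frozen random sigmoid layer
  (500 units, U(−1, 1)) is appended. Step 3: `β = pinv(O₃) T` on the
  training output of that layer. Step 4: predict by `argmax(O₃ β)`.

k-means itself is delegated to scikit-learn (10 restarts, seeded); the
analytic heads, the backprop engine and the optimiser are implemented in
the package and cross-checked against independent least-squares and
eigendecomposition solvers in the tests.

## Metrics and PCA

Macro-precision and macro-recall are unweighted means of the per-grade
ratios (a never-predicted grade scores precision 0 with a warning). The
headline macro-F1 is the **harmonic mean of the two macro averages**,
2PR/(P+R) — this identity, rather than the per-class-mean F1, is what the
published result tables satisfy row by row; the per-class mean is also
reported for transparency. On a class-balanced evaluation set accuracy
equals macro-recall exactly.

PCA is the eigendecomposition of the covariance of column-centred stable
values (no variance scaling by default, matching the protocol's silence
on standardisation; a correlation-matrix option exists). Contribution
rate of component j is λ_j/Σλ as a percentage; loading signs are fixed by
making each column's largest-magnitude entry positive so reports are
reproducible.

## Desk-scale training sizes

The published protocol trains for 8000 full-data epochs; the estimator
defaults keep that number, but the test suite and the acceptance script
run the same models at desk scale: minibatches of 512 with 60 epochs for
the hybrid (the loss has plateaued by then on these cohorts), 150–600
epochs for the small BPNN/RBF fits, and the full 240/102-fruit cohort
sizes throughout. Label-recovery checks use the default separability 1.0
cohorts and 3 seeds; the model-ranking comparison uses separability 0.5
and medians over 5 seeds.

## Known limitations

* Real-pear accuracies cannot be reproduced (dataset not deposited); all
  model-quality statements are relative to synthetic cohorts.
* The generator's grade classes are unimodal Gaussian-noise families;
  real odour classes are likely multimodal and drift over storage time.
* SMOTE on the test set is kept for protocol fidelity despite being
  statistically questionable; use the original-test path for honest
  generalisation estimates.
* The hybrid's pre-training head makes Step 1 equivalent to training a
  small BPNN; representations that help a softmax head are assumed to
  also help the random-feature least-squares head.
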