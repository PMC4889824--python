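# Methods

## Problem and signal model

`gesturekit` classifies six basic hand gestures — hand closing (HC), hand
opening (HO), wrist flexion (WF), wrist extension (WE), index-finger
straightening (IF), and thumb straightening (T) — from two-channel surface
electromyography recorded over the flexor carpi radialis and extensor carpi
radialis longus. The target acquisition setting is a consumer biofeedback
device streaming at 16 Hz. A 16 Hz stream cannot carry raw surface EMG (whose
spectral content lies mostly between 20 and 450 Hz); it is necessarily a
processed, nonnegative envelope such as a running RMS. The toolkit's data
model is agnostic to this, but the synthetic generator commits to the
envelope interpretation: gesture activity is a nonnegative activation level
per channel, not a zero-mean interference pattern.

## Segmentation

Recordings are cut into consecutive non-overlapping ("sliding") windows of
187.5 ms. At 16 Hz that is exactly `round(0.1875 × 16) = 3` samples, the
minimum length at which every implemented feature is defined (slope sign
change needs one interior point). The trailing remainder shorter than one
window is discarded. Windows overlapping more than one annotation are
labelled by the **majority** policy (the label covering most samples; ties go
to the earlier-starting annotation; unannotated samples count as rest, which
only wins an outright majority). A **strict** policy that drops mixed windows
is available. Windows outside any annotation are labelled `REST` and excluded
from classification by default, since the classifier distinguishes the six
gestures only.

## Time-domain features

For a window x_1..x_N, per channel:

* **MAV** = (1/N) Σ |x_i| — mean absolute value.
* **WL** = Σ_{i<N} |x_{i+1} − x_i| — waveform length.
* **WAMP** = #{i < N : |x_i − x_{i+1}| ≥ θ_w} — Willison amplitude, θ_w in
  signal units.
* **SSC** = #{1 < i < N : (x_i − x_{i−1})(x_i − x_{i+1}) ≥ θ_s} — slope sign
  changes, θ_s in squared signal units.

The indicator thresholds are free parameters of this toolkit. Defaults:
θ_w = 5% of the training-set median per-channel MAV (scale-adaptive, because
device units vary between hardware), and θ_s = 0 with the comparison floored
at ε = 10⁻¹² so that exact-zero products from repeated samples are not
counted as slope reversals. Both are overridable in `FeatureConfig`.

Feature vectors are channel-major (all selected features of channel 1, then
channel 2, …), which fixes the dimension ordering that models and
fingerprints depend on. Feature scaling defaults to *none*; a z-score
normalizer (fitted on training data only, zero-spread dimensions passed
through) is available because RBF kernels are scale-sensitive.

## Classifier

One-against-all soft-margin kernel SVM. Kernels:

| family      | K(u, v)                        | tuned parameters        |
|-------------|--------------------------------|-------------------------|
| quadratic   | (γ⟨u,v⟩ + c₀)²                | γ, c₀, C                |
| polynomial  | (γ⟨u,v⟩ + c₀)^d               | γ, c₀, d ∈ {2..5}, C    |
| rbf         | exp(−γ‖u−v‖²)                 | γ, C                    |

"Quadratic" is the polynomial family pinned at degree 2. One binary machine
is trained per class (that class versus all others, unweighted by default;
an inverse-prevalence weighting flag exists for the 1:(K−1) imbalance). A
test point gets the label of the machine with the largest real-valued
decision score; exact ties go to the earlier class in first-appearance
order. The binary quadratic programs are solved by scikit-learn's libsvm
backend with the iteration count capped at 10⁶ — well-posed problems at this
scale converge orders of magnitude sooner; the cap only binds on degenerate
kernels (e.g. a near-constant Gram matrix under a huge box constraint),
which would otherwise iterate indefinitely during hyperparameter search.
Fitted machines are reduced to plain support-vector / dual-coefficient /
intercept arrays, so prediction runs through the package's own kernel code
and models serialise to JSON.

A model's support-vector count is the number of training points with
nonzero dual coefficient, summed over the binary machines; the per-class
mean divides by K.

## Cuckoo Search model selection

The kernel family and its parameters are selected by Cuckoo Search, a
population metaheuristic with Lévy-flight proposals, a fixed nest count,
probabilistic abandonment of poor nests, and elitism.

**Encoding.** Kernel index {0,1,2} and degree {2..5} are integers relaxed to
the real line and rounded on decoding; C ∈ [2⁻⁵, 2¹⁵] and γ ∈ [2⁻¹⁵, 2³] are
searched in log₁₀ space; c₀ ∈ [0, 10] is linear.

**Fitness.** The 10-fold cross-validated multiclass rate on the training
side, maximised; on an exact rate tie the candidate with fewer support
vectors wins, and a full tie keeps the incumbent. Fold assignments are
re-drawn from the fitness RNG stream at every evaluation, so the fitness is
mildly stochastic — each evaluation sees a fresh random partition of the
training data rather than a cached one.

**Dynamics.** Per iteration each nest emits one Lévy proposal
`x′ = x + s·(hi−lo) ⊙ L(α) ⊙ (x − x_best)` clipped to bounds, compared
against a randomly chosen nest and installed if better. A proposal with zero
displacement (a nest sitting exactly at the best) is a no-op and is skipped:
evaluating it would only inject exact duplicates of the elite into the
population through the random-replacement rule, which freezes the search
once the duplicates take over. Then each non-elite nest is abandoned with
probability p_a and rebuilt by the biased walk
`x + U(0,1) ⊙ (x_{π₁} − x_{π₂})` over two random permutations of the
population. The best nest always survives, so the best-fitness trace is
monotone. Lévy steps use Mantegna's algorithm, `u/|v|^{1/α}` with
u ~ N(0, σ_u²), v ~ N(0,1) and the standard closed form for σ_u.

Note that a single Mantegna draw is a normal variance mixture, not a sample
of the α-stable law itself; in particular at α = 2 the σ_u prefactor
vanishes (sin(πα/2) = 0) and draws collapse toward zero rather than becoming
Gaussian. The Gaussian limit holds for sums of many steps, not per draw. The
tests therefore check the σ_u closed form and the tail-weight ordering in α
rather than per-draw normality.

**Defaults.** 25 nests, p_a = 0.25, α = 1.5, step fraction 0.01 of each
dimension's internal range, 50 iterations. These follow the canonical
description of the algorithm. The benchmark and verification runs in this
repository use smaller budgets (8 nests × 6 iterations, about 60–70 fitness
evaluations) because on the synthetic task the fitness plateaus at the
ceiling within a handful of iterations and the remaining budget only
tightens the support-vector tie-break.

## Experimental procedure

1. Split the segment dataset into training and testing halves, stratified by
   gesture (default test fraction 0.5; the proportion is a config knob).
2. Baselines: each kernel family at declared defaults (γ = 1/(d·Var(X)),
   C = 1, c₀ = 1 for polynomial families, degree 3 for the general
   polynomial) for each feature combination (MAV; WL; MAV+WL+WAMP;
   MAV+WL+SSC).
3. CS run: optimise the kernel on the training side (fitness above), refit
   the winner on the full training side, score the test side.
4. Repeat over fresh splits; report per-gesture rates, their mean, the SD of
   the mean rate across repeats, and the mean support-vector count per class.

A per-gesture table entry is the **one-vs-rest binary rate** of that class's
machine on the test set — the only reading under which a per-gesture rate is
defined for every machine independently; the per-class recall of the
multiclass prediction is computed behind `rate_mode="multiclass_recall"`.
The Mean column is the arithmetic mean of the six per-gesture rates. The
multiclass accuracy is reported alongside.

## Synthetic data generator

The generator emulates the acquisition protocol: per gesture repetition, a
rest baseline (envelope 0), a one-sample onset (optionally jittered), a 5 s
hold at the gesture's per-channel activation level, and return to rest;
6 gestures × 20 repetitions at 16 Hz by default. Sample value = envelope +
|N(0, noise_sd)| (half-normal, keeping the stream nonnegative like an RMS
output). Defaults: noise_sd = 0.1 signal units, rest 2 s, no onset jitter.

The activation template places HC/WF flexor-dominant, HO/WE
extensor-dominant, and IF/T as low-amplitude mixed activations forming the
deliberately closest pair — so the finger gestures remain the hardest
classes, a qualitative emulation of the real difficulty ordering. The
template is scaled so the minimum pairwise row distance equals
`class_separation × 0.1` signal units; the default `class_separation = 6`
puts the closest pair six reference-noise SDs apart, which is separable but
not degenerate at the three-sample window size.

What the generator does **not** emulate: inter-subject and inter-session
variability, electrode shift, amplitude drift and fatigue, cross-talk
between sites, and the true amplitude statistics of the six gestures (which
were never published). Passing tests therefore demonstrate the correctness
and the qualitative behaviour of the pipeline — optimised kernels at or
above every fixed-kernel baseline, far fewer support vectors, MAV dominating
WL, chance-level collapse under label permutation — not expected accuracy on
real recordings.

## Numerical and design choices

* Window length in samples is `round(window_ms/1000 × fs)`; a window below 3
  samples is a configuration error.
* Index convention: 0-based, half-open intervals everywhere.
* Overlapping segmentation is not implemented; it is only recommended for
  windows above 200 ms, longer than anything used here.
* Stratified splits preserve class proportions within one sample per class.
* If a class has fewer members than the fold count, the fold count degrades
  to that class size (never below 2).
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the config objects; identical seeds give bit-identical datasets, searches
  and reports.
* Decoded log-scale values are clamped to their declared bounds to absorb
  the final-ulp drift of `10**log10(x)`.
* One egg per cuckoo per iteration; abandonment rebuilds are unconditional
  (the rebuilt nest replaces its predecessor regardless of fitness), with
  the elite exempt.

## Known limitations

* The per-gesture rates of the baseline tables depend on the declared
  default kernel parameters; no claim is made that they are the best
  achievable fixed-kernel results.
* The CS variant searches a fixed mixed space; conditional parameters
  (degree and c₀ are meaningless for RBF) are carried along and ignored
  when decoding an RBF solution, which slightly dilutes the search.
* At three samples per window, WAMP ∈ {0,1,2} and SSC ∈ {0,1}; these
  features carry little information at this sampling rate and exist mainly
  for completeness and for higher-rate data.
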