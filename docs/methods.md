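# Methods

This note documents the models, algorithms and design choices of the
`visuohaptic` package: what each component assumes, which knobs matter, and
what the synthetic-data tests do and do not establish.

## Experimental designs

**Inventories.** An inventory holds `n_h` horizontal and `n_v` vertical true
pairs over `2(n_h+n_v)` integer shape ids, plus the same number of pseudo
pairs. Each horizontal pseudo pair takes the *top* shape of one vertical true
pair and the *bottom* shape of a different one (mirrored for vertical pseudo
pairs), so pseudo pairs exactly partition the shape set and never reproduce a
true pair. The donor matching is cyclic after a seeded permutation of donor
order; any matching respecting the two-different-donors-and-roles rule is
equivalent for every downstream analysis, and the cyclic rule is the simplest
deterministic one. Both counts must be ≥ 2 (a single donor cannot supply two
different pairs).

**Exposure-scene enumeration.** Visual exposure scenes place three distinct
true pairs on a 3×3 grid subject to: (1) every pair has at least one cell
edge-adjacent (4-neighbourhood — shapes are displayed with no gaps, so
corner contact does not join pairs) to a cell of another pair; (2) the centre
cell is occupied; (3) scenes identical up to translation are the same scene
(no rotation or reflection identification). Enumeration is brute force over
pair triples × anchor positions (≈ a few thousand placements, milliseconds),
canonicalized by translating the bounding box to the origin. For the standard
3+3 inventory this yields 444 scenes — 42 with three same-orientation pairs,
108 with two aligned same-orientation pairs plus one orthogonal, 72 with the
two offset, per orientation family — and every pair appears in exactly 222
scenes. The test suite re-derives the same set with an algorithmically
independent enumerator (6-cell subsets → domino partitions → identity
assignment) and re-checks every scene with a standalone validator.

**Design generators** are exhaustive-by-block: a haptic-exposure block is the
full product {same-orientation pair combinations} × {arrangement orders} ×
{pulling directions} (48 trials: 8 true-true, 8 pseudo-pseudo, 32
true-pseudo); a familiarity block compares every true pair to every
same-orientation pseudo pair in both presentation orders (36 trials for the
3+3 inventory, 16 for 2+2); the pulling tests are 2 × 24 clamp-catch trials
(12 unique ordered two-true-pair scenes × 2 directions) after visual
exposure, and one 48-trial clamp block mirroring an exposure block after
haptic exposure. Pseudorandomization is a seeded uniform shuffle within
block, with no further constraints. Stimulus timings (700 ms display, 1 s
pause, 3 s hold) are carried as metadata constants only.

## Haptic bond model

Every occupied cell belongs to one object (true pair = one two-cell object;
pseudo-pair shapes = two one-cell objects; training rectangles/squares per
visible piece). Breakage force = Σ over the two contacts crossed by the
mid-line split of 11.25 N (same object) or 3.75 N (different objects). This
reproduces the task's three levels — 22.5 N (two true pairs, pull parallel to
their orientation), 15 N (true + pseudo, hard direction), 7.5 N (all
orthogonal pulls, pseudo + pseudo, and C4 training scenes) — exactly. Forces
are static thresholds; spring dynamics and force traces are out of scope
because only the threshold enters any analysis. The 40 N measurement cap and
the 5 N pull-onset threshold live in `BondConfig` and are applied by the
simulator and the measures, not by the force rule.

## Synthetic cohort (generative behavioral model)

The simulator is the package's own construction: it exists so that every
analysis stage can be exercised against known ground truth, and its defaults
emulate the published study's scale (20 participants per experiment, 48
pulling-test and 72/32 familiarity trials). Per participant, a latent
learning strength θ ~ Beta(a, b) (default a = b = 2: broad, mean 0.5) drives
both tasks:

* **Pulling:** force = (1−θ_eff)·7.5 N + θ_eff·B_int + N(0, σ_pull²),
  clipped to [0, 40] N. B_int is the breakage force implied by the
  participant's *internal* inventory; a naive participant always pulls the
  7.5 N separation force. Default σ_pull = 4 N — comparable to the ~9 N
  between-level force differences observed in such tasks, giving the modest
  single-participant correlations real cohorts show.
* **Familiarity:** the internally-true pair is chosen with probability
  0.5 + (p_max − 0.5)(1 − e^(−θ_eff/λ_gen)) (defaults p_max = 0.98,
  λ_gen = 0.35); when neither or both presented pairs are internally true the
  choice is a fair coin. Internal truth is arrangement-specific (orientation
  and left/right–top/bottom roles), matching the definition of a pair as a
  fixed spatial configuration; without this, a swapped 2+2 inventory is
  set-equal to the pseudo pairs and the swap would (wrongly) erase all
  familiarity structure.
* **Wrong-but-consistent participants:** with probability `swap_probability`
  (default 0.1) the internal inventory has the `first` shapes of two
  same-orientation true pairs exchanged; such participants behave
  consistently with the wrong objects in *both* tasks — the signature the
  object-consistency statistic detects.
* **Cross-modal attenuation:** θ_eff = θ·transfer_gain (default 0.6) in the
  generalisation test of each experiment (haptic test after visual exposure;
  familiarity test after haptic exposure), θ otherwise. This one
  multiplicative gain reproduces the qualitative asymmetry that cross-modal
  performance is weaker, without modelling cue conflict mechanistically.
* **Explicitness:** debriefing identifications ~ Binomial(n_true_pairs,
  θ·explicit_rate)/n_true_pairs (default explicit_rate = 0.5), yielding the
  0…1 grid a debriefing produces.

What the simulator does **not** emulate: trial-order learning during tests
(performance is stationary by construction), reaction times, force-trace
dynamics, attention lapses, and any mechanistic account of how chunks are
learned. Passing tests therefore certify the *analysis pipeline* — not that
real cohorts follow this generative model.

`simulate_from_refb` bypasses the behavioral layer entirely and draws
(ρ, T_c, T) triples straight from the observation model, for
parameter-recovery and calibration studies.

## Measures and screening

Fraction correct f_c = T_c/T over familiarity trials. Pulling performance is
the **Pearson** correlation ρ between (40 N-clipped) pulling force and
breakage force — Pearson because with two equal-count force levels it is
monotonically equivalent to the two-sample t statistic,
t² = ρ²(n−2)/(1−ρ²), an identity the suite checks to 1e−10. Zero-variance
force series yield an explicit undefined flag, never a silent zero. The
block-trend check is a paired t-test of second minus first test block with a
JZS Bayes factor. Exclusion (visual-exposure experiment) requires a positive
clamp-catch training correlation with two-sided p < 0.05 — the two-sided
reading of "significant positive correlation" is the conservative one, and is
recorded per participant with its reason.

## Rectified exponential-binomial fitting and inference

* **Optimizer:** L-BFGS-B with analytic gradients on the negative
  log-likelihood, bounds β ∈ [1e−4, 1−1e−4], λ ∈ [1e−3, 10], from 20 starts
  (19 Latin-hypercube + one moment-based: β₀ from the pooled rate of ρ ≤ 0
  participants, β₁ from the top ρ-quartile, λ = 0.3). Ties break by highest
  log-likelihood then smallest λ. The binomial coefficient is retained in the
  likelihood so absolute marginal-likelihood values are well defined; it
  cancels in ratios. Probabilities are clamped at 1e−9 before logs;
  ceiling participants (f_c = 1) are retained — the binomial handles them.
* **Hessian:** central finite differences of the negative log-likelihood,
  step 1e−4 per coordinate (relative above 1), symmetrized.
* **LRT:** χ² = 2(ℓ_full − ℓ_null) against χ²(2); the null (constant success
  probability = pooled rate) is closed-form. λ is unidentified under the
  null, so the χ²(2) reference is an approximation; simulation at the study's
  size (N = 20, T = 72, 2,000 replicates) puts the type-I error within
  [0.03, 0.07] at the nominal 0.05 level, which the acceptance suite
  re-measures.
* **Profile band:** 100,000 draws from the Laplace approximation
  N(θ̂, H⁻¹); draws whose log-likelihood falls more than q/2 below the
  maximum are rejected, q the 95th percentile of χ²(3) (3 = number of
  estimated parameters); the band is the pointwise extrema of P(ρ) over
  retained draws (the ML point is always retained), clipped to [0, 1]. A
  non-positive-definite Hessian triggers logged diagonal regularization.
* **Laplace Bayes factor:** log₁₀ BF = [ℓ_full − ½ log det H_full − ℓ_null +
  ½ log det H_null]/ln 10. This is the standard Laplace ½·log-determinant
  correction with constant (2π)^{d/2} and prior factors dropped; the test
  suite verifies the kernel against a dense grid integral after adding those
  constants back. (A literal reading of "divided by the square root of the
  log-determinant" is dimensionally incoherent; the standard form is used.)
* **Range coverage:** (P(1) − P(0))/0.5.

Recovery at the study's scale (200 cohorts, N = 20, T = 72, ρ ~
U(−0.1, 0.9), true parameters 0.55/0.95/0.3) gives median sup-norm curve
error ≈ 0.03 and median |bias| of the betas ≈ 0.02 — the acceptance suite
asserts ≤ 0.05 and ≤ 0.03.

## Object consistency and explicitness

Per unique ordered two-true-pair pulling-test scene (12 after visual, 4
after haptic exposure): haptic score = mean break-direction force − mean
separate-direction force; familiarity score = mean over the scene's two pairs
of each pair's choice fraction (denominator = trials in which that pair
appeared; by design every pair appears equally often). Consistency is the
Pearson correlation of the two scores across scenes — deliberately agnostic
to whether the participant's objects are the *correct* ones. Participants at
familiarity ceiling have zero score variance and are flagged undefined, not
scored. The group test is a two-sided one-sample t against 0, pooled across
experiments (pooling changes only the degrees of freedom), with a JZS Bayes
factor.

The power study for this statistic uses cohorts in which every participant
acts on a swapped inventory with strong learning and modest noise
(θ ~ Beta(12, 2), σ_pull = 2 N): correct-inventory participants have *no*
scene-level structure (all two-true-pair scenes are statistically identical
for them), so they can only dilute a power study; the all-swapped cohort
isolates the property under test. The matched null destroys the cross-modal
link by permuting the familiarity scores across scenes within participant,
preserving both marginals.

Explicitness = correctly identified true pairs / total true pairs (0 for
participants who noticed nothing; incorrect identifications ignored, erring
toward *over*-stating explicit knowledge). The cross-modality correlation
R_full allows experiment-specific intercepts with a common slope (computed on
within-experiment-centred performances); R_partial repeats this after
residualizing both performances on explicitness within each experiment;
R²_partial/R²_full is the share of the generalisation effect attributable to
implicit transfer. With a single experiment the analysis degrades to a plain
correlation with a warning.

## JZS Bayes factors

One-sample/paired, two-sample (effective N = n₁n₂/(n₁+n₂)) and
Zellner–Siow regression Bayes factors are computed by adaptive quadrature of
the one-dimensional mixture-of-g integrals after mapping (0, ∞) → (0, 1) via
g = u/(1−u), absolute tolerance 1e−8. The default Cauchy prior scale is
√2/2 (the conventional default; configurable and recorded in every result).
The suite checks all three forms against an independent dense fixed-grid
quadrature (1e−6 relative) and cross-checks the t forms against pingouin.

## Numerical conventions and degenerate inputs

Seeds are explicit everywhere (designs, cohorts, fits, bands); identical
seeds give byte-identical trial logs and reports. File writes are atomic
(temp-file-then-rename). Degenerate situations raise or flag rather than
guess: all-ρ ≤ 0 data flag λ/β₁ unidentifiability, zero-variance series flag
undefined correlations, optimizer failures raise with per-start diagnostics,
non-positive-definite Hessians raise (Bayes factor) or regularize with a
warning (band).

## Known limitations

* The LRT's χ²(2) reference is asymptotic and only simulation-checked at the
  study's own size; very small cohorts may be miscalibrated.
* The profile band is a Monte-Carlo approximation whose accuracy depends on
  the Laplace proposal; far from the quadratic regime (tiny N, boundary
  optima) it can under-cover.
* The simulator's cross-modal gain is a single scalar; it cannot express
  asymmetric or trial-dependent transfer.
* Reported real-cohort statistics from the original study (e.g. group-level
  t values or χ²(2) = 265-scale likelihood ratios) require the deposited
  behavioral data and are outside what synthetic cohorts can or should
  reproduce; the suites here verify the machinery, not those numbers.
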