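# Methods

## Signal model and epoching

A recording is a channel × sample matrix in microvolts at a stated sampling
rate (500 Hz in the reference protocol).  Emotion annotations are integer
second spans `(start, end, label)`, **inclusive at both ends**: a span
`0:43–0:52` contains ten labelled seconds.  This convention is forced by the
reference schedules' published per-emotion sample counts (e.g. a
`1:17–2:21` span must yield 65 epochs) and is applied uniformly: epoch *k*
of a span `(s, e)` covers samples `[(s+k)·rate, (s+k+1)·rate)`.  Seconds
outside any span are simply unlabelled and produce no epochs.  Units pass
through untouched — the entropy tolerance scales with each epoch's own
standard deviation, so no unit conversion can change any downstream number.

## Entropy statistics

For an epoch `x(1..N)` (N = rate·1 s), templates of length `m` are compared
under the Chebyshev distance.  With tolerance `r = 0.15·STD` (population
STD, divisor N, computed **per epoch**; whether the original protocol used
per-epoch or per-recording STD is unstated — per-epoch follows from
defining r on "the series being measured"):

* **ApEn** counts matches with *strict* `d < r`, includes the self-match
  (so every count ≥ 1 and the logarithm is always defined), uses
  `N−m+1` templates at level m and `N−m` at level m+1, and returns
  `φ^m − φ^{m+1}` where `φ` is the mean log match fraction.
* **SampEn** excludes self-matches, with divisor `N−m` per template and the
  mean over `N−m+1` templates at level m (`N−m−1` and `N−m` at level m+1),
  returning `ln A^m − ln A^{m+1}`.

Strict `<` is kept as the defining convention even though classical
formulations use `≤`; for continuous-valued data the two differ only on a
measure-zero set, but fixtures with exact ties (alternating ±1) do depend
on it, and the tests pin it.

Numerical conventions:

* **Constant epochs** (zero peak-to-peak range) return 0 for both entropies
  with a warning — all templates are identical, so "perfect regularity" is
  the only consistent reading, and it avoids a 0 < 0 match failure under
  strict inequality.
* **Zero SampEn match counts** at either level are floored at the smallest
  attainable positive mean (one matching ordered pair: `1/((N−m)(N−m+1))`
  at level m) with a warning; this keeps the statistic finite, bounded and
  order-preserving.
* Degeneracy is detected by `ptp(x) == 0` rather than `std == 0`, because a
  constant series can carry a ~1e−16 floating-point std.

The vectorized implementation shares one pairwise-difference pass between
both entropies and both template lengths; the test suite proves it equal to
an independent naive O(N²) enumeration to 1e−9 over 100+ random epochs at
N ∈ {50, 100, 500}, together with affine invariance (`x → a·x + b`, a ≠ 0)
to the same tolerance.

## Classification

KNN with K = 2 and Euclidean distance, implemented directly so the
tie-breaking contract is explicit and deterministic: a split vote falls
back to the nearest neighbour's label (generalised for K > 2: the tied
label with the nearest representative), and equidistant neighbours at the
K-boundary are admitted by lowest training-row index after a stable sort.
Cross-validation shuffles rows once with the configured seed and splits
them into ten near-equal folds — random and **unstratified**, so severe
class imbalance (a 10-epoch emotion against 120 others) degrades exactly as
it would under the original protocol.  No feature scaling is applied before
KNN (none is part of the protocol); confusion matrices are row-normalised
percentages.

## Channel selection (binary PSO)

Particles move in `[−10, 10]^D` with velocities clamped to `[−4, 4]`,
`c₁ = c₂ = 1.49445`, inertia `λ = 1` (no damping — the position clamp
bounds the swarm; optional linear decay exists but defaults off).  `r₁, r₂`
are drawn per particle *per dimension* per iteration (the scalar notation
of the usual update equations is ambiguous; per-dimension is the common
reading).  Positions decode to masks by `sigmoid(x) > 0.5`, i.e. `x > 0`
strictly.  Fitness is the mean 10-fold CV accuracy restricted to the two
entropy columns of each selected channel; the empty mask scores 0 to keep
deselection pressure on.

Two deliberate design choices where the protocol is silent:

* **One fixed fold partition per run**, derived from the PSO seed, instead
  of re-randomised folds per evaluation.  This makes fitness a
  deterministic function of the mask, so memoization by bit-pattern is
  sound and the global-best trace is *exactly* monotone.
  `refold_per_eval=True` restores the literal re-randomising reading.
* **Ties keep the earlier incumbent** (strict improvement only), for
  reproducibility.

No convergence criterion is defined beyond the iteration budget; an
optional stagnation patience exists but defaults off.  Default swarm sizes:
50 particles × 100 iterations at 30 channels (the study profile); the
bundled small profile used throughout the tests is 20 × 30 at 10 channels,
sized so the full suite completes quickly while the 2^10 mask space is
still non-trivially searched.

## Consensus indices

Subjects' optimal masks are keyed by channel *name* (a subject missing a
channel is an error, never silently dropped).  The common-set threshold is
stored as a fraction (0.6 of the group, ceiling) with an integer override;
at ten subjects this reproduces the six-of-ten rule.  FRSOC is each
channel's selection count divided by the average per-channel count, so its
mean over channels is exactly 1 and FRSOC/OCSR is a constant
(`n_subjects·n_channels / total`) across channels — both asserted as
invariants.  Default classification thresholds: principal iff FRSOC ≥ 1.25
and OCSR ≥ 0.70; weak iff FRSOC ≤ 0.70 and OCSR ≤ 0.40.

The bundled reference index table carries two known typographic slips
(F7/CP6 printed as 0.096 where the defining formula gives 0.964, and an O1
row inconsistent between count and index); the implementation follows the
defining formula and the affected cells are excluded from exact assertions.

## Synthetic data generator

Each channel is `s(t) = ρ·osc(t) + (1−ρ)·noise_sd·w(t)`: a unit-RMS sum of
2–3 seeded sinusoids (1–40 Hz) mixed with unit-variance Gaussian noise.
Emotion is encoded **only** as the regularity weight ρ, switching at
segment boundaries on informative channels and centred on a constant
(0.5) on null channels — amplitude effects would be invisible to the
affine-invariant entropies and are deliberately excluded.  Defaults: 10
channels (first ten montage names), 4 informative, ρ = 0.7 vs 0.3 for the
two emotions (gap 0.4), 100 one-second epochs per emotion, 500 Hz.

ρ additionally receives independent Gaussian jitter per 1-s epoch
(`rho_jitter = 0.15`, clipped to [0, 1], label-independent on every
channel).  Without it a single informative channel separates the classes
perfectly and every mask containing one scores 1.0 — nothing like the
70–85% accuracy regime the method is built for, and a flat landscape for
the optimizer.  With it, single-channel accuracy sits near 0.85 and the
full set near 0.96, so multi-channel evidence genuinely pays off.

What the generator does **not** emulate: 1/f spectra, volume conduction and
inter-channel correlation, artifacts (blinks, EMG), non-stationary
baselines.  Passing tests therefore show the *pipeline machinery* recovers
planted regularity structure under realistic overlap; they do not certify
performance on real EEG.

## Problem sizes and runtime choices

The test suite and examples use the small synthetic profile (10 channels,
200 epochs, 20-particle/30-iteration swarms) and 3-subject groups for the
end-to-end ordering checks; these sizes were chosen as the smallest at
which every property of interest (planted-channel recovery, chance
calibration, accuracy ordering) is comfortably expressed.  The
study-scale profile (30 channels, 50 × 100 swarm) is available via
`SynthConfig.full_profile()` and `PSOConfig()` defaults.

## Known limitations

* The optional pre-filter implements a zero-phase 50 Hz notch plus a
  0.5–47 Hz band-pass.  The acquisition description calls the 0.5–47 Hz
  stage a "low-pass" while giving a two-sided band; the band-pass reading
  is implemented but the stage defaults off and no downstream number
  depends on it (entropy is affine-invariant, and the band edges are
  documented rather than assumed as intent).
* BrainVision round-trips are exact only to float32 storage precision; the
  delimited-matrix dialect round-trips bit-exactly and is the portable
  format.
* Headline recognition accuracies of the original recordings cannot be
  reproduced without the raw EEG; everything combinatorial (epoch
  arithmetic, common sets, FRSOC/OCSR, principal/weak classification) is
  reproduced exactly from the bundled tables, and the behavioural claims
  are checked as properties on synthetic data.
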