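# Methods

`dgpop` analyses binarized calcium-event recordings from large neural
populations — the motivating setting is miniscope imaging of dorsal
dentate-gyrus granule cells at 3 Hz, ~70 neurons per animal, mean event
rates near 0.02 Hz — during open-field exploration and a forced-alternation
T-maze. This note documents the models, estimators, defaults and numerical
choices, and what the synthetic-data generator does and does not emulate.

## Conventions

Lengths are in cm, times in seconds, rates in events/s. Angles are radians
in (−π, π] with north (+y) at 0, increasing toward west (−x):
`direction = atan2(−dx, dy)`. Event trains are 0/1 vectors at the frame
rate; an "event" (calcium transient) is treated as the unit of neural
activity throughout.

## Synthetic-data generator

The generator exists so every analysis stage is testable end-to-end without
external recordings. Its defaults emulate the statistical structure of the
recordings: 30-min open-field sessions at 3 Hz in a 40 × 40 cm arena (arena
size is configurable; 40 cm is a typical mouse open field), 70 neurons with
0.02 Hz mean event rate, graded mixed selectivity, and 50-trial T-maze
sessions with a 71.4% correct-alternation rate.

**Trajectory.** An Ornstein–Uhlenbeck speed process (mean 4 cm/s,
relaxation 0.5 s⁻¹, diffusion 3 cm·s⁻³ᐟ², reflected at 0) with a diffusing
heading (1.5 rad/√s) and reflecting walls. These defaults put substantial
occupancy in all three speed classes used by the analysis ([0,1), [1,5),
≥5 cm/s) and visit essentially all of a 10 × 10 occupancy grid within a
session.

**Tuning and events.** Each neuron's instantaneous rate is a baseline times
three modulation factors: a Gaussian place bump `1 + g·exp(−d²/2w²)`, a
linear speed ramp floored at zero, and a von-Mises-shaped direction factor
with unit circular mean. The modulation product is normalized to unit mean
over the session's occupancy, so `baseline_rate` *is* the neuron's expected
mean event rate regardless of tuning strength — tuning redistributes events
rather than adding them. Events are drawn per frame by Bernoulli thinning
of the inhomogeneous Poisson rate (`p = rate·Δt`, clipped to [0, 1] with a
logged warning when clipping occurs). Each neuron uses a deterministic
sub-stream spawned from the session seed, so neuron *i*'s train does not
depend on the population size.

`make_tuning_spec` draws per-type tuning strengths under three
coding-structure models: `independent` (strengths independent across
types), `dependent` (positively coupled through a shared per-neuron
latent), and `exclusive` (each neuron strong in at most one type).
`make_concentrated_spec` builds the configuration used by the
structure-recovery analysis: strong place tuning in a random 30% of
neurons, strong speed tuning in a disjoint 30%, the rest untuned, with
elevated rates (0.3 Hz) and wide fields (8–12 cm) so per-neuron information
is estimable in 600-s sessions. The cohort simulator draws a per-animal
lognormal tuning-quality multiplier (σ = 0.8), emulating the substantial
between-mouse spread in tuning and decoding accuracy seen in vivo.

**T-maze.** A schematic maze (40-cm stem, 20-cm arms) with a fixed per-trial
timeline: forced turn at 6 s, free-choice turn at 18 s, 24-s trials, which
leaves room for the full 5-s forced-arm window and the full 6→1-s decision
window. Forced sides are uniform; the free choice is the opposite side with
probability `correct_rate` (a trial is correct iff the choice differs from
the forced side). Neurons with nonzero LR gains are modulated by
`1 + gain·pref·side` inside the corresponding window only.

**What the generator does not emulate:** fluorescence kinetics (events are
ideal, not detected from synthetic ΔF/F), spatial correlations between
neighboring cells, slow drift and nonstationarity, theta/behavioral
rhythmicity, and error-trial dynamics beyond the choice labels. Passing
tests therefore validate the *analysis machinery* under the assumed
statistical structure; they are not evidence about biological recordings.

## Behavioral states

Speed and motion direction come from frame-to-frame displacements after a
3-frame (1-s) centered moving average of the positions, which suppresses
tracking jitter at 3 Hz. Frames with displacement below threshold have
undefined direction and are excluded from direction tuning and information.
Position is discretized on an equal-area 10 × 10 grid (half-open cells),
speed into the three classes above, and direction into eight π/4-wide arcs
centered on 0, ±π/4, ±π/2, ±3π/4, π.

## Tuning summaries

Spatial maps are occupancy-normalized event rates on a 1-cm raster, smoothed
with a Gaussian kernel (σ = 2.0 cm, truncated at 3σ) and normalized to each
neuron's maximum. Smoothing is occupancy-weighted — the smoothed rate is
`G∗(rate·occ) / G∗(occ)` with a reflecting boundary — which avoids leakage
into unvisited territory and conserves the occupancy-weighted mean rate
exactly (with smoothed occupancy as the weight). Whether the displayed maps
in the motivating work smooth the event density or the rate is ambiguous;
weighted rate smoothing was chosen because it keeps rare-visit pixels from
dominating. Speed and direction curves are events-in-class over
time-in-class; classes with zero occupancy are flagged undefined.

## Information content

The per-event (Skaggs-style) information of a neuron over a discrete state
variable is

    I = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄),   λ̄ = Σᵢ pᵢ λᵢ  [bits/transient]

summed over bins with at least 1 s of occupancy (occupancy probabilities
renormalized over included bins; rate estimates in rarely visited bins are
unstable). Neurons with zero events have undefined information and are
excluded from population tests.

Per-neuron significance uses a circular-shift null: the event train is
rotated relative to behavior by a uniform offset in [20 s, T − 20 s]
(1000 shuffles by default), preserving the train's internal temporal
statistics; a neuron is "significant" if its observed value exceeds the
95th percentile of its own null. For state-independent neurons this
exceedance is calibrated at ~5% (verified at the emulated in-vivo scale:
0.02 Hz, 1800 s). Circular shifting (rather than inter-event-interval
shuffling) is the standard null for tuning significance; the minimum shift
guards against residual behavioral autocorrelation.

The population-level test compares the observed mean information with
replicate means formed by drawing one null value per neuron
(1000 replicates, +1-smoothed p-value, floored at 1/1001 and hence
reported as "< 10⁻³" when no replicate reaches the observed mean). The
effect size is Cohen's d between the observed values and the per-neuron
null means, pooled-SD form.

## LR analysis

The forced-arm period is the 5 s after the forced turn (side label =
current arm); the decision period is 6 to 1 s before the free-choice turn
(side label = the side chosen *afterwards*, i.e. the future location). Both
windows are 15 frames at 3 Hz; trials whose window does not fit inside the
session are excluded rather than truncated, keeping per-trial exposure
constant. Correct and error trials are pooled (labels, not correctness,
enter the analysis).

The LR index is `(r_L − r_R)/(r_L + r_R)` with `r_side` the total event
count over total window time on that side — bounded in [−1, 1], sign-
symmetric under label swap, and invariant under uniform rate scaling. A
neuron silent in both conditions gets index 0 with an `inactive` flag. The
formula is isolated behind one function so an alternative normalization can
be swapped in. Significance uses a trial-label permutation null (side
labels shuffled across trials, preserving L/R counts — the exchangeable
null for trial-structured data), thresholded at the 95th percentile of
|null|.

## Decoding

Continuous variables are regressed per frame from a sliding window of
population event vectors (default 10 frames ≈ 3.3 s, ending at the decoded
frame); direction is regressed as (sin θ, cos θ) and recomposed with atan2,
avoiding the 2π discontinuity. Cross-validation uses 5 contiguous temporal
folds so autocorrelated frames do not leak across the train/test boundary;
all reported predictions are out-of-fold. T-maze left/right is decoded per
trial from the window count vectors with leave-one-trial-out
cross-validation.

Two models are provided: `linear` (ridge regression / logistic
classification; deterministic, the default for analyses and tests) and
`feedforward` (one-hidden-layer MLP, 64 units). Metrics: position — mean
absolute Euclidean error (cm); speed — Pearson correlation; direction —
mean absolute circular error (rad, in [0, π]; π/2 for uniformly random
predictions); LR — percent of trials correct.

Chance levels follow the shuffled-data convention: the identical decoder is
retrained on data whose event trains were independently circularly shifted
per neuron (open field) or whose training-trial side labels were permuted
(T-maze), then evaluated against the *true* held-out targets; the chance
value is the mean over 10 repetitions by default. For position this sits
close to the occupancy-centroid predictor, as it should.

## Deletion analysis

Neurons are deleted under a named order — by decreasing or increasing
per-neuron score (information content or |LR index|) or at random — and the
decoder is retrained from scratch on the survivors at each retention level
(100% down to 10% by 10). Retraining on the surviving dataset (rather than
zeroing inputs of a fixed decoder) matches deleting neurons *from the
dataset*. Deletion is nested; the random order is the average of several
independent draws (10 by default; 5 in the packaged cohort experiment,
which stabilizes the baseline at a quarter of the cost). The linear decoder
is the default inside deletion analysis for tractability (hundreds of
retrainings); for the packaged cohort experiment the feature window is 5
frames.

Two orders are compared by Cohen's d (unpaired, pooled SD) across animals
at the nine levels 90..10%, summarized as the mean |d|; the orders × orders
matrix of mean |d| is the independence fingerprint: when an information
type lives in its own subpopulation, the same-type descending order is far
from random (large |d|) while a different type's order stays close to it.
In the packaged structure-recovery experiment the same-type contrast
exceeds the cross-type contrast by roughly an order of magnitude in every
seed. One caveat discovered during validation: with *strictly disjoint*
tuned subpopulations the cross-type order is not exactly exchangeable with
random — deleting only the other type's cells spares the decoded variable's
cells relative to random deletion, so the cross-type |d| is small but
systematically positive (~0.5 at the default conditions) rather than ~0.

The deletion-order ANOVA averages performance across animals per
(order, level) cell and analyses the 5 × 10 layout as a two-way ANOVA
without replication (residual = interaction), giving the order factor
df = (4, 36); Tukey–Kramer pairwise comparisons of order means use the
studentized range on the residual mean square. Degenerate layouts
(identical curves) report F = 0, p = 1.

## Event detection

The ΔF/F detector exists so the pipeline can ingest fluorescence fixtures;
it is intentionally minimal (no motion correction or source separation).
Onsets are threshold crossings at median + 4 MAD; a candidate is accepted
only if the trace stays above threshold for ≥ 0.2 s after the excursion's
peak, rejecting noise blips. A constant trace (MAD = 0) yields no events
with a warning.

## Problem sizes and numerical notes

Packaged experiments and tests run at desk scale by design: 300–900 s
sessions for decoding checks, 600-s sessions × 7 animals × 70 neurons for
the structure-recovery cohort, 1800 s × 200 neurons for null calibration.
Shuffle computations are vectorized over event indices (a 1000-shuffle null
for a sparse neuron costs ~1 ms). Permutation p-values are floored at
1/(n+1); Cohen's d with zero pooled SD returns 0 for equal means and ±inf
otherwise; ridge duplicated-feature near-invariance holds to O(α).

## Known limitations

No recurrent sequence decoder is provided (the linear and feedforward
models are; accuracy differences between decoder families were not material
to any packaged analysis). The event detector is not a substitute for a
full imaging pipeline. The generator's independence structures are
idealized endpoints; real populations show graded mixtures. Speed
information uses only three classes, so its dynamic range is small compared
to the 100-bin spatial variable.
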