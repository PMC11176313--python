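# Methods

This note documents the model, the estimators, the synthetic data, and the
numerical choices behind `wirevo`, including where the design was genuinely
open and what the desk-scale defaults do and do not show.

## Circuit model

The reservoir has `n_units = 48` units, 16 per subtype (input / hidden /
RC-readout), with input routed one-to-one onto the input units and the
linear readout reading the RC-readout units. The update is the leaky-tanh
form

    x(t+1) = (1 − α) x(t) + α (W r(t) + β u(t) + σ ξ),   r = tanh(x)

with α = 0.1 (decay coefficient), β = 1.0 (input gain), σ = 0.01 (noise
std), x(0) = 0. A pure-accumulator variant (`update_rule="integrator"`,
x(t+1) = x(t) + α W r + β u + σ ξ) is retained for comparison but is not
the default: without a leak every driven state integrates its input
monotonically, tanh saturates within tens of steps, activations freeze and
stimulus-to-readout information flow vanishes — no information-maximization
experiment is possible in that regime. The readout reads the bounded
activations r of the RC-readout units by default (`readout_activation=
"state"` switches to raw x); readout weights start N(0, 1).

Internal weights are initialized sparse — each entry nonzero with
probability s = 0.2, values Uniform[−0.5, 0.5] — and rescaled to spectral
radius exactly 1. Every pattern produced by initialization, crossover or
mutation is re-normalized before it enters evaluation; the spectral radius
is *not* re-normalized after Hebbian tuning, which perturbs it only at the
~1e−3 level under spontaneous activity.

Self-connections are permitted and treated like any other entry.

## Spatial layout and structural metrics

Units occupy a 3-layer stack of 4×4 grids (one subtype per layer, input at
the bottom, RC-readout at the top), unit spacing 1. Adjacent units — by
default including diagonal neighbors, the 26-neighborhood — are at
distance 1, and the full distance matrix D comes from Warshall-Floyd over
those unit-length adjacencies (equivalently, Chebyshev distance on this
box). The diagonal-inclusive choice is deliberate: with it, the mean
coupling cost of fresh default patterns is ≈232, matching the experiment's
pre-evolution operating point of ≈250; restricting adjacency to
axis-aligned neighbors (`adjacency="orthogonal"`) yields Manhattan
distances and a mean cost of ≈412, incompatible with that operating point.

Coupling cost is C = Σ_ij |W_ij| D_ij. The absolute value is used so
inhibitory connections cannot cancel excitatory cost — C is a penalty and
must be nonnegative; `signed=True` computes the literal signed sum for
audit. Density counts nonzero entries over all n² cells (a flag excludes
the diagonal). Newman modularity is maximized greedily (CNM, via networkx)
on the symmetrized absolute-weight graph |W| + |W|ᵀ with self-loops
dropped.

Clustering coefficient and mean shortest path length are computed on the
**directed** binarized connection graph: the Fagiolo directed local
clustering averaged over units, and the mean distance over reachable
ordered pairs. At density 0.2 a random directed graph has clustering ≈0.20
and path ≈1.92, which is the regime the experiment reports (≈0.2 / ≈2.0);
the undirected reading (`directed=False`) inflates the effective edge
density to ≈0.36 and gives ≈0.36 / ≈1.64 instead.

## Hebbian plasticity

One subtractive-normalized rule serves both plasticity phases:

    τ dw/dt = v u − v (n·u) n / N,   τ = 0.1

Every increment sums to zero across the N upstream units, conserving each
downstream unit's total incoming weight. "Activity" means the bounded tanh
activations throughout; for readout training the downstream activity is
v = tanh(z_i) (raw z is available via `readout_activity="linear"`, but
because z = W_out r̂ its use makes the weight growth multiplicative with a
nonnegative exponent r̂·(r̂ − mean) and the weights overflow within a few
hundred driven steps — tanh-bounding makes growth at most linear).

Integration is forward Euler, one update per model timestep, with default
step **dt = τ = 0.1**. This is the largest stable Euler step for a rule
with time constant τ: steps well beyond τ (e.g. dt = 1, rate dt/τ = 10)
discretize the ODE unstably, and on a reservoir held at the marginal
stability boundary ρ(W) = 1 the resulting online positive feedback
occasionally (≈1% of tuning runs) amplifies a noise-excited near-marginal
mode into full tanh saturation, blowing the weights up by two to three
orders of magnitude — a numerical artifact, not a behavior of the modeled
system, and one that would dominate the bottom-of-population statistics.

Reservoir tuning runs 100 steps (`T_tune`) of spontaneous, noise-driven
activity with zero external input and updates only entries that were
already nonzero (mask-preserving, N = 48 upstream units), so tuning never
changes the density. A flag lifts the mask restriction. Readout training
drives the network with the saccade series and updates each readout row
with the N = 16 RC-readout activations as upstream activity; no supervised
target exists anywhere in the pipeline.

## Information estimators

TE, MI and NMI use plug-in (maximum-likelihood) estimates on equal-width
discretizations, log base 2. Each series is binned over its own range into
`n_bins = 8` bins (a constant series occupies a single bin and contributes
zero information). Transfer entropy is the standard expectation

    TE(X→Y) = Σ p(y_{t+1}, y_t^(k), x_t^(l)) log₂
              [ p(y_{t+1} | y_t^(k), x_t^(l)) / p(y_{t+1} | y_t^(k)) ]

with history lengths k = l = 1 by default and no bias correction. The
pattern-level objective runs the trained pattern on a validation series
and sums TE from each of the 16 input signals to each of the 16 RC-readout
activations (`aggregate="mean"` divides by 256).

Two properties of this convention are worth knowing:

- *Bias*: the plug-in estimate is biased upward roughly in proportion to
  the number of occupied histogram cells over the sample count. With 8
  bins and k = l = 1 the bias is negligible at 10⁴ samples, ≈0.05 bits per
  pair at 2,000 samples, and substantial below a few hundred. Tests that
  assert "TE ≈ 0 for no pathway" therefore use 2,000-step series.
- *Lag*: a stimulus entering an input unit first affects an RC-readout
  activation two steps later (routing, then one synapse), and the leak
  spreads the response further. With l = 1 the estimator therefore credits
  a pattern through the autocorrelation of the stimulus stream (saccade
  clips within a scene are correlated) rather than through the
  instantaneous causal link; this ranks patterns consistently but
  compresses the dynamic range between wired and unwired circuits. Longer
  source histories (l ≥ 2) expose the direct pathway.

NMI(C, K) = I(C;K) / √(H(C) H(K)) is computed directly from label
frequencies; a single-class labeling is rejected (zero entropy). Entropy
summation is done in sorted-count order so MI is exactly symmetric in its
arguments.

## NSGA-II

Objective vectors are in minimization convention (TE negated). Fast
non-dominated sorting and crowding distance follow the standard algorithm;
survivor selection takes whole fronts in rank order and resolves the
splitting front by descending crowding. Parents are chosen by binary
tournament on (rank, crowding) — `parent_selection="uniform"` draws them
uniformly from the survivors instead, since the source experiment states
only that parents are "randomly selected".

Crossover tiles the weight matrix into aligned, non-overlapping 2×2 blocks
starting at (0, 0); each block is copied whole from either parent with
probability 1/2, and the child is re-normalized to ρ = 1. Mutation hits
80% of offspring; it picks one aligned 2×2 block and either zeroes it
(probability 0.5) or refills it with fresh entries at the initial sparsity
and Uniform[−0.5, 0.5] values, then re-normalizes. The block count per
mutation event is configurable.

The run starts from P + Q fresh patterns; each cycle selects P survivors,
breeds Q offspring, evaluates them (normalize → tune → train readout →
measure TE on the validation series → structural record on the tuned
weights), and re-pools. Survivors keep their records and are not
re-evaluated; the tuned weights are the heritable genome. All randomness
derives from the master seed through per-(generation, index, stream)
`SeedSequence` children, so runs are exactly reproducible.

Pattern accounting follows the source experiment's convention that the
initial pool is generation 1: a Gen-generation run touches
(Gen − 1)·Q + P + Q patterns — 25,250 at the published Gen = 100,
P = Q = 250.

## Synthetic stimuli

Surrogate landscapes are spectrally shaped Gaussian noise with 1/f
amplitude spectra — the canonical second-order statistic of natural
images — min-max rescaled to [0, 1]. They reproduce natural images'
spatial correlation structure but none of their higher-order structure
(edges, occlusions, phase alignment); conclusions about e.g. orientation
selectivity of evolved circuits under *real* natural input are outside
what these tests can show.

The saccade series extracts square scene windows (default 16×16) at random
positions and, within each scene, shifts a 4×4 clip window by uniform
integer offsets in [−scene/4, +scene/4] per axis (clamped inside the
scene), one linearized clip per timestep. "Clip size 4" is read as a 4×4
patch — 16 pixels mapping one-to-one onto the 16 input units. The probe
set holds each of eight oriented bars (two placements each of horizontal,
vertical, diagonal-down, diagonal-up) for `n_hold = 20` steps with fresh
uniform [0, 0.1] noise per step, separated by 20-step blanks; the value of
the hold length is a package default, chosen so each stimulus contributes
enough samples for the 3-PC embedding while the full probe stays at 320
steps.

## Characterization

The probe trajectory of the whole reservoir (activations, standardized per
unit; constant units dropped with a warning) is projected onto its first
three principal components. Fractal dimension is the least-squares slope
of log N(ε) vs log(1/ε) over 8 logarithmically spaced box sizes between
bounding-cube edge/2 and edge/64; the grid exactly covers the bounding box
(upper-face points are clipped into the last box). Finite point sets
saturate the count when boxes outnumber points, flattening the slope —
values well below the attractor's true dimension are expected for short
probes and are comparable only within a fixed convention. Separation NMI
clusters the non-blank embedded points with k-means (k = number of
stimuli, 10 restarts, seeded) and scores against the true labels; blanks
are embedded but not clustered. Trajectory volume counts occupied voxels
on a grid shared across the compared entities (edge/50) and divides by the
maximum so the largest trajectory has volume 1.

## Desk-scale defaults and what they show

The full published scale (Gen = 100, P = Q = 250, 20,000-step training
series) is supported but slow; tests and the acceptance script use the
"desk" preset: Gen = 10, P = Q = 25, one surrogate landscape × 50 scenes ×
40 clips = 2,000 training steps, 800 validation steps, ≈30 s on one core.
At this scale the run reproduces the *stable* quantities faithfully —
initial cost ≈232, density 0.19–0.20 every generation, clustering ≈0.19,
path ≈1.95, rising TE and falling cost trends — but ten generations of
selection move mean coupling cost only ≈10% (the full-scale experiment
needs its hundred generations for the ≈60% decline), and the top/bottom-TE
entities are barely differentiated, so contrasts that full-scale runs
resolve (bottom entity separating better than top; sub-unity fractal
dimensions of strongly clustered trajectories) are weak or absent at desk
scale.

## Known limitations

- The TE operating scale depends entirely on the estimator convention
  (bins, histories, aggregation); only relative comparisons under a fixed
  convention are meaningful.
- Unsupervised Hebbian readout training finds high-variance directions but
  its weight scale grows without bound (linearly, under the bounded-
  activity default); z is meaningful up to scale, which PCA-based analyses
  standardize away.
- The readout layer's size (16 outputs) mirrors the RC-readout pool; the
  source experiment never states it.
- Community detection is greedy and can miss the global modularity
  optimum; Q values are lower bounds.
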