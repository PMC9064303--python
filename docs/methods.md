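# Methods

`infoflow` estimates directed information flow between spike trains in
continuous time and tracks how that flow emerges, locks in, and
specialises as a network develops.  This note records the models,
estimators, parameter choices and their rationale, the design decisions
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Transfer entropy on point processes

For a target spike train X and source Y observed on a window of length
τ, the transfer entropy rate can be written as a sum over the N_X target
spikes of the log ratio of the target's instantaneous firing rate
conditioned on (target, source) history versus target history alone:

    TE(Y→X) = (1/τ) Σ_i ln [ λ(x_i | x_<t, y_<t) / λ(x_i | x_<t) ]   (nats/s)

Histories are represented by interspike-interval embeddings: at an
observation time t, the target part is the vector of l_X intervals
(t − t₁, t₁ − t₂, …) over the most recent target spikes before t, and
the source part likewise with l_Y intervals.  This representation keeps
the full time resolution of the data while spanning seconds of history
with a handful of coordinates — with a mean interval of 0.71 s and
l_X = 4, the target history spans ≈ 2.84 s on average, which a binned
representation at the raw 40 µs resolution could not reach.

By a Palm-calculus identity, each conditional-rate ratio equals a ratio
of history densities sampled *at target spikes* versus *at uniformly
random times*, so the TE rate is a difference of two Kullback–Leibler
divergences:

    TE = (N_X/τ) [ D(joint@spikes ‖ joint@random) − D(target@spikes ‖ target@random) ]

### The shared-radius k-NN realisation

The two divergences live in different dimensions (l_X + l_Y versus
l_X).  Estimating them independently with Kozachenko–Leonenko k-NN
estimators and differencing does **not** work at realistic sample
sizes: the small-sample bias of each divergence grows with dimension,
and the difference inherits a bias we measured at ≈ −2.5 nats/s on
independent 1 Hz Poisson pairs — three orders of magnitude above the
signal floor.  `estimate_te_rate` therefore uses a shared-radius,
digamma-corrected scheme: for each target spike, the radius ε_i is the
max-norm distance to its k-th nearest neighbour among the joint
embeddings at spikes; neighbours strictly within ε_i are counted in the
joint@random (n_Jr), target@spikes (n_Ts) and target@random (n_Tr)
samples, and the per-spike contribution is

    ψ(k) − ψ(n_Jr + 1) − ψ(n_Ts + 1) + ψ(n_Tr + 1).

Because one radius is shared by all four density estimates, the
kernel-volume terms cancel exactly, in the same way the
Kraskov–Stögbauer–Grassberger mutual-information estimator cancels
them across marginal spaces.  The TE rate is the sum of these
per-spike "local contributions" divided by τ, so the identity
`te_rate · τ = Σ locals` holds to machine precision by construction;
burst-local TE (below) relies on it.  Measured null bias on Poisson
pairs is ≈ −0.01 nats/s at N_X ≈ 100–3600, removed in reported point
estimates by subtracting the surrogate mean.

Parameters, with defaults and reasons:

| parameter | default | meaning / rationale |
|---|---|---|
| `l_x` | 4 | target history intervals; consensus choice from AIS maximisation |
| `l_y` | 2 | source history intervals; consensus choice from TE maximisation |
| `k_global` | 10 | neighbour count; stable bias/variance for this family |
| `n_u_factor` | 50 | random samples per spike (N_U = 50·N_X); dense bursts need many samples |
| `n_u_surr_factor` | 10 | spike-anchored pool per spike for the resampling surrogate |
| `k_perm` | 10 | neighbour candidates per spike when resampling source histories |
| `n_surrogates` | 100 | null replicates; Gaussian fit extrapolates beyond 1/100 |
| `anchor_noise` | 0.24 s | half-width of spike-anchored sampling offsets |

Estimation refuses data with exact ties in embedding space (a
`TiedDistanceError` tells the user to jitter): acquisition clocks
quantise spike times, and `jitter_spike_times` dithers by ± half a grid
step (default ±20 µs for a 25 kHz clock) to restore almost-sure
uniqueness without moving any spike beyond its quantisation error.

### Active information storage

AIS — the information a train's own past carries about its present —
uses the second divergence alone, rate-weighted:
`AIS = (N_X/τ)·D(target@spikes ‖ target@random)`, here estimated with
the Kozachenko–Leonenko divergence form (`knn_divergence`).  Its bias
is removed by subtracting the mean raw AIS of rate-matched memoryless
surrogates: the same number of spikes redistributed uniformly over the
window, each surrogate estimated end to end on its own train.  The
memoryless train is the exact zero-storage null, and a full re-estimate
per surrogate reproduces the sample geometry of spike-conditioned
queries, which a cheaper "reshuffle the embeddings" correction does
not (we measured that shortcut leaving +0.5 nats/s of spurious storage
on Poisson trains; the full-surrogate correction leaves the null within
sampling error of zero while preserving the positive storage of regular
renewal trains).

## Significance testing

The null hypothesis for a pair is conditional independence of the
target from the source.  Surrogate TE replicates are drawn and the
p-value is the upper tail of a Gaussian fitted to the 100 surrogate
values — counting cannot resolve the family-wise threshold of
0.01/3422 ≈ 2.9×10⁻⁶, which is why the Gaussian fit is used.

Two surrogate constructions are implemented:

- **rotation** (default): the source train is circularly time-shifted
  by an offset uniform on [0.1τ, 0.9τ] (histories wrap through the
  window edge) and the estimator re-evaluated with all target-side
  structures held fixed.  This preserves both marginal processes
  exactly and destroys only their alignment, making the surrogate
  statistic exchangeable with the observed one under the null.  On 60
  independent Poisson pairs the observed-minus-surrogate-mean gap was
  +0.002 ± 0.004 nats/s, the empirical false-positive rate at the 95th
  surrogate percentile 0.067, and uncorrected p-values consistent with
  Uniform(0,1) (KS p = 0.9).
- **local_permutation**: each target spike's source embedding is
  replaced by that of one of its `k_perm` nearest neighbours in
  target-history space, drawn without replacement within a replicate.
  This is the classical conditional-permutation construction; it
  preserves the target process and its self-history structure but, at
  desk-scale spike counts, the reassembled source parts lose the
  temporal-overlap correlations of time-locked samples and the null
  distribution shifts high by ~0.01–0.03 nats/s (anticonservative
  p-values).  It is retained for comparison and for large-N use; the
  calibrated rotation scheme is the default everywhere.

A functional network keeps, for every ordered node pair, the TE rate if
its p-value clears the Bonferroni-corrected family level (default
family α = 0.01 over n·(n−1) tests; 3422 for 59 nodes) and exactly zero
otherwise.  `n_tests` always uses the retained node count; the value
used is recorded on the network object.

## Burst analysis

Node bursts: scanning spikes in order, a burst opens at spike s_i when
s_i − s_{i−k} < α (the last k+1 spikes span less than α) and closes at
the earlier spike of the first interval exceeding a·α, or at the last
spike.  α defaults to half the node's mean interspike interval,
1/(2·rate), computed per node: a k-spike span shorter than half the
typical interval is unambiguously bursty.  Presets: cultures use
k=2, a=3, β=15, γ=10; the model's far more stereotyped dynamics use
k=1, a=1.5, β=2, γ=1.  Results are insensitive to moderate changes in
these values; a population-mean α is available via `BurstParams.alpha`.

Population bursts: an event-driven sweep over node-burst endpoints
opens a burst when the count of simultaneously bursting nodes first
exceeds β and closes it when the count drops below γ, with boundaries
at the crossing endpoints.

Mean burst position ranks nodes within each population burst by the
time of their first in-burst spike (rank 1 = earliest, ties broken by
node label) and averages each node's rank over the bursts it spiked in.
First-spike rank is the natural statistic for "leader/follower"
semantics; nothing in the downstream analyses depends on the
tie-breaking order because post-jitter ties have probability zero.

Burst-local TE restricts the per-spike local contributions to target
spikes inside population bursts and averages per spike (nats/spike
rather than nats/s), making flows during bursts comparable across nodes
with different rates.  Surrogate burst-local values are computed from
surrogate local contributions in exactly the same way, which yields
both a significance gate and a bias correction for burst-local totals.

## Embedding-length selection

One consensus l_X and l_Y are used for all nodes and sessions so that
estimation bias is comparable everywhere.  Starting at l = 1, the
candidate length grows while the mean bias-corrected AIS across nodes
(for l_X), or mean surrogate-mean-subtracted TE across ordered pairs
(for l_Y), increases significantly at p < 0.05 under a paired two-sided
t-test across the units (pairing matches "increase across the
electrodes"; Welch's unpaired test is available as a flag).  The
selection trace (mean, SD, p, accepted per candidate) is returned as a
table.  The shipped defaults l_X = 4, l_Y = 2 are the consensus values
this procedure selects on representative culture data, so running the
selection is optional.

## The synthetic developing network

`stdp_sim` emulates the statistical structure of MEA recordings from a
developing culture: 59 recording nodes, rates spanning a broad range,
10³–10⁴ spikes per node per 50 s analysis window, and a developmental
transition from near-independent tonic firing to network-wide
population bursts.  It is a network of Izhikevich neurons (v in mV,
t in ms; v' = 0.04v² + 5v + 140 − u + I, u' = a(bv − u), reset
v←c, u←u+d at 30 mV) with all-to-all excitatory coupling, no
self-connections, no delays, and additive pair-based STDP with
exponential windows (τ± = 20 ms), amplitudes A± = 4×10⁻⁴ per unit
trace, and hard clipping to [0, g_max] with g_max = 10.

Choices behind the unpinned constants:

- **Neuron**: the standard regular-spiking set a=0.02, b=0.2, c=−65,
  d=8.  Constant drive of 46 (±3% per-neuron heterogeneity, the seed's
  only role besides initial states) produces independent tonic firing
  near 100 Hz uncoupled.
- **Synapses**: conductance-based with 0 mV reversal and 3 ms decay —
  recurrent drive self-limits as neurons depolarise.  Each presynaptic
  terminal carries a short-term depression resource (release fraction
  0.5, recovery 1 s): resource depletion is what terminates a
  population burst, and its recovery time sets the quiescence between
  bursts.  Without depression, an ignited all-to-all network of this
  coupling strength fires continuously and never returns to baseline.
- **STDP amplitudes** are absolute weight increments.  Weight growth is
  driven by causal spike correlations: once a weight is large enough to
  advance its target's spikes, potentiation compounds, so development
  is sigmoidal — quiet for hundreds of seconds, then a transition to
  collective bursting.
- **Integration**: forward Euler at dt = 0.5 ms with the classic
  two-half-step membrane update, the membrane clamped at the 30 mV
  spike cut for stability under strong recurrent input.  The kernel is
  a numba-compiled loop; a 550 s, 59-neuron run takes seconds.

With the default configuration the run reproduces the study narrative:
the early window (200–250 s) contains no population bursts, the mid
window (400–450 s) is where bursting begins to emerge, the late window
(500–550 s) is dominated by pronounced, nearly synchronous bursts, and
the median spike count per neuron per window is ≈ 5.4×10³ (seeds 0–2:
5437–5483), matching the reported median of 5170 to within ~6%.

What the generator does **not** emulate: multi-unit aggregation (each
node is one neuron, not an electrode's mixture), inhibitory neurons,
conduction delays, distance-dependent topology, and the irregular burst
timing of real cultures (model bursts are markedly more regular).
Passing tests on this generator therefore demonstrate that the
estimators and statistics recover known structure under realistic
rates, burstiness and development — not that they would behave
identically on any particular biological dataset.

## Longitudinal statistics

- Lock-in: Spearman rank correlation between sessions of edge-level TE
  (all ordered pairs, zeros kept for non-significant edges) or of
  per-node mean outgoing/incoming TE.  Sessions with fewer than 10
  significant TE values are excluded wherever the 10-value gate
  appears, identically everywhere.
- Computational roles: per node, the in/out burst-local totals (with
  non-significant pairs zeroed), their ratio out/(in+out) (1 =
  transmitter, 0 = receiver, 0.5 = mediator), and Spearman correlations
  of burst position with inward/outward totals, optionally restricted
  to positions beyond a cutoff.
- Mean-TE comparisons between sessions use the two-sided two-sample
  Student's t-test on full TE vectors (zeros included); the caller
  supplies the Bonferroni family size.
- Counts of significant results across a family are tested against
  Binomial(n, α) with tail probability P(≥ k); stars mark tail < 0.05
  (\*) and < 0.001 (\*\*) after the caller's Bonferroni factor.
  Family sizes are configurable because they differ per analysis
  family (day pairs within a culture, panels within a figure set).
- Distribution summaries report the mean TE and significant-edge count
  on unmodified values; quartiles and the Gaussian-kernel density
  (bandwidth = 10% of the data range) describe nonzero values with
  > 10 SD outliers excluded.

Spearman and t statistics are delegated to scipy (average-rank tie
handling, t-approximation p-values) and are pinned by brute-force
oracle tests to 1e-12 on small instances.

## Numerical and degenerate-input conventions

- Observation windows are half-open [t_start, t_end): consecutive
  windows never double-count a spike.
- Observation points without full-length histories are redrawn
  (random sampling) or skipped (target spikes); τ remains the full
  window length.  The effect vanishes for N_X ≫ l_X.
- Max-norm distances on raw (unscaled) interval coordinates: all
  coordinates share units of seconds.
- Every stochastic step draws from its own seeded generator keyed by
  (node pair, purpose), so pairwise results are reproducible and
  independent of evaluation order.
- Zero-rate nodes are skipped in burst detection; nodes in no
  population burst have undefined (absent) positions; zero in-burst
  spikes make burst-local TE undefined (absent) — all logged, never
  silently zeroed.

## Problem sizes used in the shipped test and acceptance runs

Unit and property tests run on small synthetic instances (Poisson and
relay pairs of 10²–10³ spikes, τ = 100–600 s).  The estimator
calibration suite uses 200 independent Poisson pairs (τ = 120 s, 100
surrogates each) for false-positive-rate and uniformity checks, 20
pairs at τ = 600 s for the null mean, and 10 relay seeds for
directionality.  The developmental pipeline checks run the full 550 s
default simulation once and estimate TE on a subsample of neurons over
short window slices with reduced random-sample factors and surrogate
counts; these choices keep the whole suite within minutes while leaving
every scientific check intact.  The full-scale protocol (all 3422
pairs × 3 windows × 100 surrogates) is a many-hour computation and is
exposed through the same functions and CLI for users who want it.
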