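# infoflow

Continuous-time information-flow analysis of developing spiking
networks.

Dissociated neuronal cultures grown on multi-electrode arrays start out
firing almost independently and, over days in vitro, develop
network-wide population bursts.  `infoflow` provides the full pipeline
for asking *when directed information flow emerges in such recordings,
whether its spatial structure locks in early, and how nodes specialise
into transmitter/receiver roles during bursts*:

- **Transfer entropy (TE) in continuous time.**  For a source Y and
  target X, the TE rate is estimated directly on the interspike
  intervals,

      TE(Y→X) = (1/τ) Σᵢ ln [ λ(xᵢ | x₍₋₎, y₍₋₎) / λ(xᵢ | x₍₋₎) ]  (nats/s),

  summing over target spikes the log ratio of the target's
  instantaneous rate with and without the source history.  Histories
  are interval embeddings (defaults: 4 target and 2 source intervals)
  and the density ratios are estimated with a shared-radius,
  digamma-corrected k-nearest-neighbour scheme, so the estimator keeps
  the raw time resolution while spanning seconds of history.  Active
  information storage (AIS) — used to select the history lengths — is
  the corresponding single-train quantity.
- **Surrogate significance testing.**  Null TE replicates preserve both
  trains' internal statistics while destroying their alignment; a
  Gaussian fit to 100 surrogates yields p-values far below 1/100, which
  Bonferroni correction over all ordered node pairs requires (59 nodes
  → 3422 tests → per-test threshold 2.9×10⁻⁶ at family α = 0.01).
  Significant pairs form a directed functional network.
- **Burst analysis.**  Interval-threshold burst detection per node, an
  event-sweep population-burst detector, mean burst position (rank of
  first in-burst spike), and burst-local TE — the average per-spike TE
  contribution inside population bursts (nats/spike).
- **Longitudinal statistics.**  Spearman lock-in correlations of edge-
  and node-level flow between sessions, transmitter/receiver role
  ratios, burst-position/role correlations, mean-TE comparisons, and
  binomial tests on counts of significant results.
- **A synthetic developing network.**  A 59-neuron all-excitatory
  Izhikevich network with additive STDP (g_max = 10, A± = 4×10⁻⁴)
  develops from independent tonic firing to periodic population bursts
  over 550 s; windows at 200–250, 400–450 and 500–550 s act as
  recording sessions of increasing age.  Every stage of the pipeline is
  testable against it without any external download.

See `docs/methods.md` for the estimators, parameter defaults, and the
reasoning behind every numerical choice.

## Worked example

Estimate information flow across a deterministic 5 ms relay (the
target repeats each source spike 5 ms later) and test it against
surrogates:

```python
import numpy as np
from infoflow import (EstimatorParams, jitter_spike_times, test_pair)
from infoflow.spike_data import recording_from_arrays

rng = np.random.default_rng(3)
src = np.sort(rng.uniform(0, 600, rng.poisson(600)))   # 1 Hz Poisson
tgt = src + 0.005                                      # relay, +5 ms
rec = recording_from_arrays([("s", src), ("t", tgt[tgt < 600])], 0, 600)
rec = jitter_spike_times(rec, seed=1)                  # dither the clock grid

fwd, surr = test_pair(rec["s"], rec["t"], EstimatorParams(seed=1))
rev, _    = test_pair(rec["t"], rec["s"], EstimatorParams(seed=1))
print(f"TE s->t {fwd.te_rate:.2f} nats/s, surrogate max {surr.values.max():.3f}, p {fwd.p_value:.1e}")
print(f"TE t->s {rev.te_rate:.2f} nats/s, p {rev.p_value:.2f}")
```

Output from this exact script:

```
TE s->t 3.02 nats/s, surrogate max 0.025, p 0.0e+00
TE t->s -0.02 nats/s, p 0.69
```

The forward direction carries ~3 nats of information per second —
every source spike fixes the timing of a target spike — and exceeds
all 100 surrogates (the Gaussian-fit p-value underflows), while the
reverse direction is indistinguishable from its null: the relay's past
adds nothing about the source beyond the source's own history.

Generate a developing-network recording and inspect its burst
structure:

```python
from infoflow import SimConfig, simulate, extract_windows, annotate_bursts

windows = extract_windows(simulate(SimConfig(seed=0)))
for name, rec in windows.items():
    ann = annotate_bursts(rec, "model")
    print(name, rec.n_spikes, "spikes,", len(ann.population_bursts), "population bursts")
```

```
early 307884 spikes, 0 population bursts
mid 318201 spikes, 86 population bursts
late 356127 spikes, 1068 population bursts
```

The same pipeline is scriptable from the shell — `infoflow simulate`,
`infoflow load`, `infoflow bursts`, `infoflow estimate`,
`infoflow select-embeddings` — each a thin wrapper over the functions
above; MEA recordings enter as two-column text files
(`node_id<TAB>time_seconds`).

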