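"""Izhikevich network developing under additive STDP.

Synthetic-data generator emulating a developing neural culture: an
all-to-all excitatory network of Izhikevich neurons that starts out as
independent tonic spikers (heterogeneous constant drive) and, through
additive exponential-window STDP with hard weight bounds ``[0, g_max]``,
self-organises into periodic network-wide population bursts.  Extracted
analysis windows early, mid and late in the run play the role of
recording sessions at increasing developmental age.

Membrane dynamics follow the standard Izhikevich form (v in mV, t in ms)

    v' = 0.04 v^2 + 5 v + 140 - u + I,   u' = a (b v - u),

with reset ``v <- c, u <- u + d`` on crossing 30 mV, integrated with the
classic two-half-step Euler update for ``v``.  Synapses are
conductance-based: each presynaptic spike increments an exponentially
decaying conductance on its targets by the synaptic weight, and the
synaptic current is ``g (E_syn - v)`` with excitatory reversal
``E_syn = 0`` mV, so recurrent drive self-limits as neurons depolarise.
Each presynaptic terminal carries a short-term depression resource
(release fraction ``std_u``, recovery time ``std_tau``) whose depletion
is what terminates a population burst and whose recovery time sets the
inter-burst quiescence; pair-based STDP potentiates a synapse on postsynaptic
spikes in proportion to the presynaptic trace and depresses it on
presynaptic spikes in proportion to the postsynaptic trace, with
amplitudes ``A±`` and hard clipping to ``[0, g_max]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from infoflow.spike_data import Recording, SpikeTrain

__all__ = ["SimConfig", "SimOutput", "simulate", "extract_windows",
           "DEFAULT_WINDOWS"]

#: Analysis windows (seconds) marking early, mid and late development.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "early": (200.0, 250.0),
    "mid": (400.0, 450.0),
    "late": (500.0, 550.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the developing-network simulation.

    The network-level settings (59 all-excitatory neurons, no synaptic
    delays, ``g_max = 10``, ``A± = 4e-4``, 550 s duration) define the
    study conditions; the single-neuron constants are the standard
    regular-spiking Izhikevich set, and the drive current is calibrated
    so each neuron fires tonically at ~10^2 Hz uncoupled, giving
    10^3–10^4 spikes per neuron per 50 s analysis window.
    """

    n_neurons: int = 59
    inhibitory_fraction: float = 0.0
    synaptic_delay: float = 0.0
    g_max: float = 10.0
    a_plus: float = 4e-4
    a_minus: float = 4e-4
    stdp_tau_plus: float = 0.020
    stdp_tau_minus: float = 0.020
    izh_a: float = 0.02
    izh_b: float = 0.2
    izh_c: float = -65.0
    izh_d: float = 8.0
    drive_current: float = 46.0
    drive_heterogeneity: float = 0.03
    syn_tau: float = 0.003
    syn_reversal: float = 0.0
    std_u: float = 0.5
    std_tau: float = 1.0
    w_init_max: float = 0.1
    dt: float = 5e-4
    duration: float = 550.0
    max_rate: float = 400.0
    snapshot_times: tuple[float, ...] = (0.0, 200.0, 250.0, 400.0, 450.0, 500.0, 550.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inhibitory_fraction <= 1.0:
            raise ValueError("inhibitory_fraction must lie in [0, 1]")
        if self.inhibitory_fraction != 0.0:
            raise ValueError(
                "only all-excitatory networks are supported "
                "(inhibitory_fraction must be 0)"
            )
        if self.synaptic_delay != 0.0:
            raise ValueError("synaptic delays are not supported (must be 0)")
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("STDP magnitudes must be nonnegative")
        if self.g_max < 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("g_max, dt and duration must be positive")


@dataclass
class SimOutput:
    """Simulation result: full-run spike trains and weight snapshots."""

    recording: Recording
    weight_snapshots: dict[float, np.ndarray]
    config: SimConfig


@njit(cache=False)
def _integrate(
    v, u, w, i_drive,
    a, b, c, d,
    g_max, eff_ap, eff_am,
    dec_plus, dec_minus, dec_syn, e_syn,
    std_u, std_rec,
    dt_ms, n_steps,
    spike_t, spike_id,
    snap_steps, snaps,
):  # pragma: no cover - exercised through simulate()
    n = v.size
    trace_p = np.zeros(n)
    trace_m = np.zeros(n)
    syn = np.zeros(n)
    res = np.ones(n)
    fired = np.empty(n, dtype=np.int64)
    count = 0
    si = 0
    for step in range(n_steps):
        if si < snap_steps.size and step == snap_steps[si]:
            snaps[si, :, :] = w
            si += 1
        for i in range(n):
            syn[i] *= dec_syn
            trace_p[i] *= dec_plus
            trace_m[i] *= dec_minus
            res[i] += std_rec * (1.0 - res[i])
        for i in range(n):
            cur = i_drive[i] + syn[i] * (e_syn - v[i])
            vi = v[i]
            vi += 0.5 * dt_ms * (0.04 * vi * vi + 5.0 * vi + 140.0 - u[i] + cur)
            if vi < 30.0:
                vi += 0.5 * dt_ms * (0.04 * vi * vi + 5.0 * vi + 140.0 - u[i] + cur)
            if vi > 30.0:
                vi = 30.0  # spike cut: amplitude above threshold is not used
            if not np.isfinite(vi):
                return -2, count, si
            u[i] += dt_ms * a * (b * vi - u[i])
            v[i] = vi
        nf = 0
        for i in range(n):
            if v[i] >= 30.0:
                fired[nf] = i
                nf += 1
        if nf == 0:
            continue
        t_s = (step + 1) * dt_ms * 1e-3
        for fi in range(nf):
            j = fired[fi]
            v[j] = c
            u[j] += d
            if count >= spike_t.size:
                return -1, count, si
            spike_t[count] = t_s
            spike_id[count] = j
            count += 1
            # deliver synaptic conductance, scaled by available resources
            for i in range(n):
                if i != j:
                    syn[i] += w[j, i] * res[j]
            res[j] *= 1.0 - std_u
            # STDP: j as post (potentiate w[:, j]), j as pre (depress w[j, :])
            for i in range(n):
                if i == j:
                    continue
                wij = w[i, j] + eff_ap * trace_p[i]
                if wij > g_max:
                    wij = g_max
                w[i, j] = wij
                wji = w[j, i] - eff_am * trace_m[i]
                if wji < 0.0:
                    wji = 0.0
                w[j, i] = wji
        for fi in range(nf):
            j = fired[fi]
            trace_p[j] += 1.0
            trace_m[j] += 1.0
    return 0, count, si


def simulate(config: SimConfig | None = None) -> SimOutput:
    """Run the developing-network simulation.

    Deterministic given ``config.seed`` (which sets the initial membrane
    states, the heterogeneous drive currents and the initial weights; the
    dynamics themselves are noise-free).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_neurons

    v = rng.uniform(-75.0, -55.0, size=n)
    u = cfg.izh_b * v
    het = rng.uniform(-1.0, 1.0, size=n)
    i_drive = cfg.drive_current * (1.0 + cfg.drive_heterogeneity * het)
    w = rng.uniform(0.0, cfg.w_init_max, size=(n, n))
    np.fill_diagonal(w, 0.0)

    dt_ms = cfg.dt * 1e3
    n_steps = int(round(cfg.duration / cfg.dt))
    dec_plus = float(np.exp(-cfg.dt / cfg.stdp_tau_plus))
    dec_minus = float(np.exp(-cfg.dt / cfg.stdp_tau_minus))
    dec_syn = float(np.exp(-cfg.dt / cfg.syn_tau))

    cap = int(cfg.max_rate * cfg.duration * n)
    spike_t = np.empty(cap)
    spike_id = np.empty(cap, dtype=np.int64)
    snap_steps = np.asarray(
        sorted(
            min(int(round(ts / cfg.dt)), n_steps - 1)
            for ts in cfg.snapshot_times
            if 0.0 <= ts <= cfg.duration
        ),
        dtype=np.int64,
    )
    snaps = np.empty((snap_steps.size, n, n))

    status, count, n_snaps = _integrate(
        v, u, w, i_drive,
        cfg.izh_a, cfg.izh_b, cfg.izh_c, cfg.izh_d,
        cfg.g_max, cfg.a_plus, cfg.a_minus,
        dec_plus, dec_minus, dec_syn, cfg.syn_reversal,
        cfg.std_u, float(1.0 - np.exp(-cfg.dt / cfg.std_tau)),
        dt_ms, n_steps,
        spike_t, spike_id,
        snap_steps, snaps,
    )
    if status == -2:
        raise FloatingPointError(
            f"membrane potential diverged; reduce dt (currently {cfg.dt} s)"
        )
    if status == -1:
        raise RuntimeError(
            f"spike buffer exhausted (mean rate exceeded {cfg.max_rate} Hz); "
            "raise max_rate"
        )

    spike_t = spike_t[:count]
    spike_id = spike_id[:count]
    width = len(str(n - 1))
    trains = {}
    for i in range(n):
        nid = f"n{i:0{width}d}"
        times = spike_t[spike_id == i]
        times = times[times < cfg.duration]
        trains[nid] = SpikeTrain(nid, times, 0.0, cfg.duration)
    recording = Recording(f"stdp-sim-seed{cfg.seed}", 0, trains)
    snapshots = {
        float(snap_steps[i] * cfg.dt): snaps[i].copy() for i in range(n_snaps)
    }
    return SimOutput(recording=recording, weight_snapshots=snapshots, config=cfg)


def extract_windows(
    out: SimOutput,
    windows: dict[str, tuple[float, float]] | None = None,
) -> dict[str, Recording]:
    """Cut the full-run recording into labelled analysis windows.

    Each window becomes its own :class:`Recording` (half-open
    ``[start, end)``, window-local bounds) with ``day`` set to the window
    start in seconds, so the windows order chronologically like recording
    days of a culture.
    """
    windows = windows or DEFAULT_WINDOWS
    duration = out.config.duration
    recs: dict[str, Recording] = {}
    for name, (t0, t1) in windows.items():
        if not (0.0 <= t0 < t1 <= duration):
            raise ValueError(
                f"window {name!r} = [{t0}, {t1}) outside run [0, {duration}]"
            )
        trains = {
            nid: tr.restrict(t0, t1) for nid, tr in out.recording.trains.items()
        }
        recs[name] = Recording(out.recording.culture_id, int(t0), trains)
    return recs
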