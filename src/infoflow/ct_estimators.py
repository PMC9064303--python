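"""Continuous-time transfer entropy and active information storage.

For a point-process target :math:`X` and source :math:`Y`, the TE rate can
be written as a sum over target spikes of the log ratio of the target's
instantaneous firing rate conditioned on (target, source) histories versus
target history alone,

.. math::

    \\dot T_{Y \\to X} = \\frac{1}{\\tau} \\sum_{i=1}^{N_X}
        \\ln \\frac{\\lambda_{x|x_{<t},y_{<t}}}{\\lambda_{x|x_{<t}}} .

Histories are represented by fixed-length vectors of interspike intervals:
the first component is the time from the observation point back to the
process's most recent spike, and subsequent components are the preceding
interspike intervals.  By a Palm-calculus argument each conditional-rate
ratio reduces to a ratio of history densities *at spikes* versus *at
uniformly random times*, so the TE rate equals

.. math::

    \\dot T = \\frac{N_X}{\\tau}\\left[
        D(\\text{joint@spikes}\\,\\|\\,\\text{joint@random}) -
        D(\\text{target@spikes}\\,\\|\\,\\text{target@random})\\right],

a difference of two Kullback–Leibler divergences.  The TE estimator
realises this difference with a shared-radius, digamma-corrected
k-nearest-neighbour scheme under the maximum norm: each target spike's
radius is the distance to its ``k``-th neighbour among the joint
embeddings at spikes, and neighbours within that radius are counted in
the joint@random, target@spikes and target@random samples, so the
kernel-volume terms of the four density estimates cancel exactly and the
per-spike contribution reduces to

.. math::

    \\psi(k) - \\psi(n_{Jr}+1) - \\psi(n_{Ts}+1) + \\psi(n_{Tr}+1).

Sharing one radius across the four sets (rather than differencing two
independent divergence estimates) is what keeps the estimator calibrated:
the small-sample bias of a k-NN divergence grows with dimension, and the
joint and target-only spaces differ in dimension, so independently
estimated divergences do not cancel their biases under the null.  AIS is
the second divergence alone (a single-dimension problem), rate-weighted,
with residual bias removed by subtracting the mean over shuffled-history
surrogates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from infoflow.spike_data import SpikeTrain

__all__ = [
    "EstimatorParams",
    "TEResult",
    "InsufficientHistoryError",
    "TiedDistanceError",
    "build_embedding",
    "interval_embeddings",
    "sample_observation_points",
    "knn_divergence",
    "estimate_te_rate",
    "estimate_ais_rate",
]


class InsufficientHistoryError(ValueError):
    """An observation point has fewer prior spikes than the embedding needs."""


class TiedDistanceError(ValueError):
    """Exact ties in embedding space break the k-NN density estimates."""


@dataclass(frozen=True)
class EstimatorParams:
    """Parameters of the continuous-time TE estimator.

    Attributes
    ----------
    l_x, l_y
        Number of interspike intervals in the target / source history
        embeddings.  The defaults (4, 2) are consensus values selected by
        maximising bias-corrected AIS / TE on a representative recording
        (see :mod:`infoflow.embedding_selection`).
    k_global
        Neighbour count for the divergence estimates.
    k_perm
        Neighbour count used when resampling source histories for
        surrogate generation.
    n_u_factor
        Random (non-spike) history samples per usable target spike;
        ``N_U = n_u_factor * N_X``.
    n_u_surr_factor
        Spike-anchored history samples per usable target spike used as the
        surrogate resampling pool.
    n_surrogates
        Surrogate replicates for significance testing and bias correction.
    anchor_noise
        Half-width (s) of the uniform offset applied to spike-anchored
        sample points, wide enough to cover a typical burst's envelope.
    seed
        Base seed; every estimate derives its own independent stream.
    """

    l_x: int = 4
    l_y: int = 2
    k_global: int = 10
    k_perm: int = 10
    n_u_factor: int = 50
    n_u_surr_factor: int = 10
    n_surrogates: int = 100
    anchor_noise: float = 0.240
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("l_x", "l_y", "k_global", "k_perm", "n_u_factor",
                     "n_u_surr_factor", "n_surrogates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.anchor_noise < 0:
            raise ValueError("anchor_noise must be nonnegative")


@dataclass
class _PairState:
    """Internal per-pair state retained for surrogate generation."""

    target: SpikeTrain
    source: SpikeTrain | None
    tgt_at_spikes: np.ndarray          # (N, l_x) target-only embeddings at spikes
    src_at_spikes: np.ndarray | None   # (N, l_y) source embeddings at spikes
    tgt_at_random: np.ndarray | None   # (N_U, l_x) target-only embeddings
    rand_times: np.ndarray | None      # the N_U random observation times
    joint_random_tree: cKDTree | None  # joint embeddings at random times
    tgt_spike_tree: cKDTree | None     # target-only embeddings at spikes
    tgt_random_tree: cKDTree | None    # target-only embeddings at random times
    n_random: int


@dataclass
class TEResult:
    """TE rate estimate for one ordered node pair.

    ``local_contributions`` are the per-target-spike log-ratio terms (nats)
    aligned with ``spike_times``; their sum divided by the observation
    length equals ``te_rate`` exactly, which is what makes burst-local
    averaging well defined.
    """

    source_id: str
    target_id: str
    te_rate: float
    local_contributions: np.ndarray
    spike_times: np.ndarray
    n_target_spikes: int
    duration: float
    params: EstimatorParams
    p_value: float | None = None
    surrogate_mean: float | None = None
    surrogate_sd: float | None = None
    state: "_PairState | None" = field(default=None, repr=False, compare=False)

    def without_state(self) -> "TEResult":
        return replace(self, state=None)


def build_embedding(train: SpikeTrain, t: float, l: int) -> np.ndarray:
    """History embedding of ``train`` at observation time ``t``.

    Returns ``(t - t1, t1 - t2, ..., t_{l-1} - t_l)`` where ``t1 > t2 > ...``
    are the most recent spikes strictly before ``t``.  Raises
    :class:`InsufficientHistoryError` when fewer than ``l`` spikes precede
    ``t``.
    """
    if l < 1:
        raise ValueError("embedding length must be >= 1")
    emb, valid = interval_embeddings(train.times, np.atleast_1d(float(t)), l)
    if not valid[0]:
        raise InsufficientHistoryError(
            f"node {train.node_id!r}: fewer than {l} spikes before t={t}"
        )
    return emb[0]


def interval_embeddings(
    times: np.ndarray, obs: np.ndarray, l: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised interval embeddings at many observation times.

    Returns ``(emb, valid)`` where ``emb`` has shape ``(n_valid, l)`` for
    the observation points with at least ``l`` spikes strictly before them
    and ``valid`` is the boolean mask over ``obs``.
    """
    idx = np.searchsorted(times, obs, side="left") - 1
    valid = idx >= l - 1
    iv = idx[valid]
    emb = np.empty((iv.size, l), dtype=np.float64)
    if iv.size:
        emb[:, 0] = obs[valid] - times[iv]
        for j in range(1, l):
            emb[:, j] = times[iv - j + 1] - times[iv - j]
    return emb, valid


def _stable_hash(label: str) -> int:
    return int.from_bytes(hashlib.blake2s(label.encode()).digest()[:4], "little")


def _rng_for(params: EstimatorParams, *labels: str) -> np.random.Generator:
    """Independent stream per (pair, purpose), stable across processes."""
    return np.random.default_rng([params.seed, *map(_stable_hash, labels)])


def sample_observation_points(
    target: SpikeTrain,
    n: int,
    mode: str = "uniform",
    anchor_noise: float = 0.0,
    seed: int | np.random.Generator = 0,
    *,
    source: SpikeTrain | None = None,
    l_x: int = 1,
    l_y: int = 0,
    max_tries: int = 1000,
) -> np.ndarray:
    """Draw ``n`` observation times with full-length histories.

    ``uniform`` mode draws i.i.d. Uniform(t_start, t_end) times; the
    ``spike_anchored`` mode cycles the target's spikes and adds
    Uniform(−anchor_noise, +anchor_noise) offsets, which concentrates the
    samples in dense (bursting) stretches of the train.  Times lacking
    ``l_x`` prior target spikes (and ``l_y`` prior source spikes when a
    source is given) are discarded and redrawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("uniform", "spike_anchored"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    n_found = 0
    spikes = target.times
    for _ in range(max_tries):
        m = max(n - n_found, 16)
        if mode == "uniform":
            cand = rng.uniform(target.t_start, target.t_end, size=m)
        else:
            base = np.resize(spikes, m)
            cand = base + rng.uniform(-anchor_noise, anchor_noise, size=m)
            cand = cand[(cand > target.t_start) & (cand < target.t_end)]
        ok = np.searchsorted(spikes, cand, side="left") >= l_x
        if source is not None and l_y > 0:
            ok &= np.searchsorted(source.times, cand, side="left") >= l_y
        cand = cand[ok]
        out.append(cand)
        n_found += cand.size
        if n_found >= n:
            return np.concatenate(out)[:n]
    raise InsufficientHistoryError(
        f"could not place {n} observation points with l_x={l_x}, l_y={l_y} "
        f"histories on node {target.node_id!r}; train too short"
    )


def _knn_log_ratios(
    samples_p: np.ndarray, samples_q: np.ndarray, k: int
) -> np.ndarray:
    """Per-point ``d * ln(nu_i / rho_i)`` terms of the k-NN divergence."""
    p = np.asarray(samples_p, dtype=np.float64)
    q = np.asarray(samples_q, dtype=np.float64)
    if p.ndim != 2 or q.ndim != 2 or p.shape[1] != q.shape[1]:
        raise ValueError("sample sets must be 2-D with equal dimension")
    n_p, d = p.shape
    if n_p <= k:
        raise ValueError(f"need more than k={k} samples in P (got {n_p})")
    if q.shape[0] < k:
        raise ValueError(f"need at least k={k} samples in Q (got {q.shape[0]})")
    rho = cKDTree(p).query(p, k=k + 1, p=np.inf)[0][:, k]
    nu = cKDTree(q).query(p, k=k, p=np.inf)[0][:, k - 1] if k > 1 else \
        cKDTree(q).query(p, k=1, p=np.inf)[0]
    if np.any(rho == 0.0) or np.any(nu == 0.0):
        raise TiedDistanceError(
            "exact ties in embedding space; apply jitter_spike_times to "
            "dither grid-quantised spike times before estimation"
        )
    return d * np.log(nu / rho)


def knn_divergence(samples_p: np.ndarray, samples_q: np.ndarray, k: int) -> float:
    """Kozachenko–Leonenko k-NN estimate of ``D(P || Q)`` in nats.

    ``D = (d/N_P) * sum_i ln(nu_i / rho_i) + ln(N_Q / (N_P - 1))`` where
    ``rho_i`` is the max-norm distance from ``p_i`` to its k-th nearest
    neighbour within P (self excluded) and ``nu_i`` the distance to the
    k-th nearest neighbour within Q.
    """
    lr = _knn_log_ratios(samples_p, samples_q, k)
    n_p = len(samples_p)
    return float(lr.mean() + np.log(len(samples_q) / (n_p - 1)))


def te_local_terms(
    joint_s: np.ndarray,
    joint_r_tree: cKDTree,
    tgt_s_tree: cKDTree,
    tgt_r_tree: cKDTree,
    l_x: int,
    k: int,
) -> np.ndarray:
    """Per-spike TE contributions by the shared-radius digamma scheme.

    For each joint embedding at a spike, the radius is the max-norm
    distance to its ``k``-th nearest neighbour among the joint embeddings
    at spikes (self excluded); neighbours strictly within that radius are
    then counted in the joint@random, target@spikes and target@random
    samples, giving ``psi(k) - psi(n_Jr+1) - psi(n_Ts+1) + psi(n_Tr+1)``
    per spike.  Summing and dividing by the observation length yields the
    TE rate.
    """
    eps = cKDTree(joint_s).query(joint_s, k=k + 1, p=np.inf)[0][:, k]
    if np.any(eps == 0.0):
        raise TiedDistanceError(
            "exact ties in embedding space; apply jitter_spike_times to "
            "dither grid-quantised spike times before estimation"
        )
    r = eps * (1.0 - 1e-12)  # strict inequality at the radius
    tgt_part = joint_s[:, :l_x]
    n_jr = joint_r_tree.query_ball_point(joint_s, r, p=np.inf, return_length=True)
    n_ts = tgt_s_tree.query_ball_point(tgt_part, r, p=np.inf, return_length=True) - 1
    n_tr = tgt_r_tree.query_ball_point(tgt_part, r, p=np.inf, return_length=True)
    return (
        digamma(k) - digamma(n_jr + 1) - digamma(n_ts + 1) + digamma(n_tr + 1)
    )


def _usable_spike_mask(
    target: SpikeTrain, source: SpikeTrain | None, l_x: int, l_y: int
) -> np.ndarray:
    """Target spikes with full-length target (and source) histories."""
    ok = np.arange(target.n_spikes) >= l_x  # index i has i spikes strictly before
    if source is not None and l_y > 0:
        ok &= np.searchsorted(source.times, target.times, side="left") >= l_y
    return ok


def estimate_te_rate(
    source: SpikeTrain,
    target: SpikeTrain,
    params: EstimatorParams | None = None,
    *,
    keep_state: bool = True,
) -> TEResult:
    """Estimate the TE rate (nats/s) from ``source`` to ``target``.

    Joint (target ⧺ source) and target-only history embeddings are sampled
    at the target's spikes and at ``N_U`` uniformly random times; the TE
    rate is the rate-weighted difference of the two spike-versus-random
    divergences.  Per-spike local contributions are retained so that
    ``sum(local_contributions) / duration == te_rate`` exactly.
    """
    params = params or EstimatorParams()
    if (source.t_start, source.t_end) != (target.t_start, target.t_end):
        raise ValueError("source and target must share an observation window")
    l_x, l_y, k = params.l_x, params.l_y, params.k_global

    usable = _usable_spike_mask(target, source, l_x, l_y)
    spike_times = target.times[usable]
    n_x = int(spike_times.size)
    if n_x <= params.k_global:
        raise InsufficientHistoryError(
            f"target {target.node_id!r} has only {n_x} usable spikes "
            f"(need > k_global = {params.k_global})"
        )

    tgt_s, v = interval_embeddings(target.times, spike_times, l_x)
    assert v.all()
    src_s, v = interval_embeddings(source.times, spike_times, l_y)
    assert v.all()
    joint_s = np.hstack([tgt_s, src_s])

    rng = _rng_for(params, source.node_id, target.node_id, "random-points")
    rand_times = sample_observation_points(
        target, params.n_u_factor * n_x, "uniform", seed=rng,
        source=source, l_x=l_x, l_y=l_y,
    )
    tgt_r, _ = interval_embeddings(target.times, rand_times, l_x)
    src_r, _ = interval_embeddings(source.times, rand_times, l_y)
    joint_r = np.hstack([tgt_r, src_r])

    joint_r_tree = cKDTree(joint_r)
    tgt_s_tree = cKDTree(tgt_s)
    tgt_r_tree = cKDTree(tgt_r)
    locals_ = te_local_terms(joint_s, joint_r_tree, tgt_s_tree, tgt_r_tree, l_x, k)
    tau = target.duration
    te_rate = float(locals_.sum() / tau)

    state = None
    if keep_state:
        state = _PairState(
            target=target,
            source=source,
            tgt_at_spikes=tgt_s,
            src_at_spikes=src_s,
            tgt_at_random=tgt_r,
            rand_times=rand_times,
            joint_random_tree=joint_r_tree,
            tgt_spike_tree=tgt_s_tree,
            tgt_random_tree=tgt_r_tree,
            n_random=joint_r.shape[0],
        )
    return TEResult(
        source_id=source.node_id,
        target_id=target.node_id,
        te_rate=te_rate,
        local_contributions=locals_,
        spike_times=spike_times,
        n_target_spikes=n_x,
        duration=tau,
        params=params,
        state=state,
    )


def estimate_ais_rate(
    target: SpikeTrain,
    l_x: int | None = None,
    params: EstimatorParams | None = None,
    *,
    n_bias_surrogates: int | None = None,
) -> float:
    """Bias-corrected active information storage rate (nats/s).

    The raw AIS rate is ``(N_X / tau) * D(target@spikes || target@random)``.
    Residual small-sample bias is removed by subtracting the mean raw AIS
    of rate-matched memoryless surrogate trains (the same number of spikes
    redistributed uniformly over the window), each estimated with the full
    procedure.  A memoryless train is the zero-storage null, and because
    each surrogate AIS is computed end to end on its own train, the
    subtraction cancels the estimator's sample-geometry bias at this
    spike count rather than only its mean level.
    """
    params = params or EstimatorParams()
    l_x = params.l_x if l_x is None else l_x
    if l_x < 1:
        raise ValueError("l_x must be >= 1")
    k = params.k_global

    def _raw_ais(train: SpikeTrain, rng: np.random.Generator) -> float:
        usable = _usable_spike_mask(train, None, l_x, 0)
        spike_times = train.times[usable]
        n_x = int(spike_times.size)
        if n_x <= k:
            raise InsufficientHistoryError(
                f"target {train.node_id!r} has only {n_x} usable spikes"
            )
        tgt_s, _ = interval_embeddings(train.times, spike_times, l_x)
        rand_times = sample_observation_points(
            train, params.n_u_factor * n_x, "uniform", seed=rng, l_x=l_x
        )
        tgt_r, _ = interval_embeddings(train.times, rand_times, l_x)
        return n_x / train.duration * knn_divergence(tgt_s, tgt_r, k)

    rng = _rng_for(params, target.node_id, "ais-random-points")
    ais = _raw_ais(target, rng)

    n_surr = params.n_surrogates if n_bias_surrogates is None else n_bias_surrogates
    if n_surr > 0:
        surr_vals = np.empty(n_surr)
        rng_s = _rng_for(params, target.node_id, "ais-surrogates")
        for b in range(n_surr):
            null_times = np.sort(
                rng_s.uniform(target.t_start, target.t_end, target.n_spikes)
            )
            null_train = SpikeTrain(
                target.node_id, null_times, target.t_start, target.t_end
            )
            surr_vals[b] = _raw_ais(null_train, rng_s)
        ais -= surr_vals.mean()
    return float(ais)
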