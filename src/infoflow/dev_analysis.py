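"""Longitudinal statistics: lock-in, computational roles, summary tables.

These are the statistics run on sequences of functional networks and
burst annotations from one culture or simulation: rank correlations of
edge- and node-level information flow between earlier and later sessions
(lock-in), correlations of burst-local TE with mean burst position
(computational roles), mean-TE comparisons between sessions, and binomial
tests on counts of significant results across a family of tests.

Sessions enter these statistics only if they carry at least
``MIN_SIGNIFICANT`` (10) significant TE values; sparser networks are
excluded (and logged) wherever the gate applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from infoflow.significance import FunctionalNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "MIN_SIGNIFICANT",
    "GateError",
    "LongitudinalSet",
    "edge_lockin",
    "node_flow_lockin",
    "role_ratio",
    "position_role_correlation",
    "mean_te_comparison",
    "significance_count_test",
    "summarize_distributions",
    "lognormality_check",
    "lockin_table",
]

#: Minimum number of significant TE values for a session to enter
#: correlation analyses.
MIN_SIGNIFICANT = 10


class GateError(ValueError):
    """A session fails the minimum-significant-values gate."""


def _check_gate(net: FunctionalNetwork, label: str) -> None:
    if net.n_significant < MIN_SIGNIFICANT:
        logger.info(
            "%s network has %d < %d significant TE values; excluded",
            label, net.n_significant, MIN_SIGNIFICANT,
        )
        raise GateError(
            f"{label} network has fewer than {MIN_SIGNIFICANT} significant "
            "TE values"
        )


@dataclass(frozen=True)
class LongitudinalSet:
    """Ordered sessions of one culture or simulation.

    ``sessions`` maps day (or window) label to that session's
    functional network; optional per-day burst annotations and
    burst-local TE totals ride along for role analyses.  All sessions
    must share the same node universe; days must be strictly increasing.
    """

    culture_id: str
    sessions: dict[int, FunctionalNetwork]
    bursts: dict[int, object] | None = None
    burst_local: dict[int, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        days = list(self.sessions)
        if days != sorted(set(days)):
            raise ValueError("session days must be strictly increasing")
        universes = {net.node_ids for net in self.sessions.values()}
        if len(universes) > 1:
            raise ValueError("sessions disagree on the node universe")

    @property
    def days(self) -> list[int]:
        return list(self.sessions)

    def edge_lockin_table(self) -> pd.DataFrame:
        return lockin_table(self.sessions, "edge")

    def node_lockin_table(self, direction: str = "out") -> pd.DataFrame:
        return lockin_table(self.sessions, "node", direction)


def edge_lockin(
    early: FunctionalNetwork, late: FunctionalNetwork
) -> tuple[float, float, int]:
    """Spearman correlation of edge TE values between two sessions.

    All ordered node pairs enter, with zeros retained for non-significant
    edges.  Returns ``(rho, two-sided p, n_pairs)``.  Either session
    having fewer than 10 significant values raises :class:`GateError`.
    """
    if early.node_ids != late.node_ids:
        raise ValueError("networks must share the same node set")
    _check_gate(early, "early")
    _check_gate(late, "late")
    x, y = early.edge_values(), late.edge_values()
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), len(x)


def node_flow_lockin(
    early: FunctionalNetwork,
    late: FunctionalNetwork,
    direction: str = "out",
) -> tuple[float, float, int]:
    """Spearman correlation of per-node mean outgoing (or incoming) TE
    between two sessions (zeros included in the node means)."""
    if direction not in ("out", "in"):
        raise ValueError("direction must be 'out' or 'in'")
    if early.node_ids != late.node_ids:
        raise ValueError("networks must share the same node set")
    _check_gate(early, "early")
    _check_gate(late, "late")
    x = early.mean_te(direction)
    y = late.mean_te(direction)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), len(x)


def role_ratio(
    burst_local_out: dict[str, float], burst_local_in: dict[str, float]
) -> dict[str, float]:
    """Per-node proportion of burst-local flow that is outgoing.

    ``ratio = out / (in + out)``: 1 marks a pure transmitter, 0 a pure
    receiver, 0.5 a balanced mediator.  Nodes with ``in + out == 0`` (or
    missing from either total) are omitted.
    """
    out = {}
    for nid in burst_local_out.keys() & burst_local_in.keys():
        total = burst_local_out[nid] + burst_local_in[nid]
        if total != 0:
            out[nid] = burst_local_out[nid] / total
    return out


def position_role_correlation(
    mean_position: dict[str, float],
    burst_local_total: dict[str, float],
    *,
    min_position: float | None = None,
) -> tuple[float, float, int]:
    """Spearman correlation of mean burst position with burst-local TE.

    Only nodes with both a defined position and a defined total enter;
    ``min_position`` optionally restricts to nodes bursting later than a
    cutoff (used to examine the role gradient away from the very earliest
    bursters).  Returns ``(rho, two-sided p, n_nodes)``.
    """
    nodes = sorted(mean_position.keys() & burst_local_total.keys())
    if min_position is not None:
        nodes = [n for n in nodes if mean_position[n] > min_position]
    if len(nodes) < 3:
        raise GateError(f"only {len(nodes)} nodes available for correlation")
    pos = np.array([mean_position[n] for n in nodes])
    tot = np.array([burst_local_total[n] for n in nodes])
    rho, p = stats.spearmanr(pos, tot)
    return float(rho), float(p), len(nodes)


def mean_te_comparison(
    te_values_a: np.ndarray, te_values_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test for a difference in mean TE.

    Both inputs are full per-pair TE vectors (zeros included for
    non-significant pairs).  A Bonferroni factor for the number of
    session pairs compared is applied by the caller.
    """
    a = np.asarray(te_values_a, dtype=np.float64)
    b = np.asarray(te_values_b, dtype=np.float64)
    if a.std() == 0 and b.std() == 0:
        raise ValueError("both samples have zero variance; t-test undefined")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def significance_count_test(
    p_values: "list[float] | np.ndarray",
    alpha: float = 0.05,
    *,
    bonferroni_factor: int = 1,
) -> tuple[int, int, float, str]:
    """Binomial tail test on the count of significant results.

    Under the null that the supplied p-values are Uniform(0, 1), the
    number below ``alpha`` is Binomial(n, alpha); the tail probability is
    ``P(Binomial(n, alpha) >= k)``.  Returns ``(k, n, tail, stars)``
    where ``stars`` is ``'**'`` if ``tail * bonferroni_factor < 0.001``,
    ``'*'`` if ``< 0.05``, else ``''``.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    n = int(p.size)
    k = int((p < alpha).sum())
    tail = float(stats.binom.sf(k - 1, n, alpha))
    corrected = tail * bonferroni_factor
    stars = "**" if corrected < 0.001 else "*" if corrected < 0.05 else ""
    return k, n, tail, stars


@dataclass(frozen=True)
class DistributionSummary:
    """Summary of one session's TE values (Table-style row plus density)."""

    mean_te: float
    n_significant: int
    n_values: int
    quartiles: tuple[float, float, float]
    n_outliers_excluded: int
    density_grid: np.ndarray | None
    density: np.ndarray | None


def summarize_distributions(
    te_values: np.ndarray, *, density_points: int = 256
) -> DistributionSummary:
    """Summary statistics and density estimate for one session's TE values.

    ``mean_te`` and the significant count use all values unmodified.  The
    quartiles and the Gaussian-kernel density describe the nonzero
    (significant) values with entries further than 10 SDs from their mean
    excluded as outliers; the kernel bandwidth is 10% of the retained
    data range.  The density is omitted when fewer than 10 nonzero values
    remain.
    """
    te = np.asarray(te_values, dtype=np.float64)
    mean_te = float(te.mean()) if te.size else 0.0
    nz = te[te != 0]
    n_sig = int(nz.size)

    n_out = 0
    kept = nz
    if nz.size >= 2:
        mu, sd = nz.mean(), nz.std(ddof=1)
        if sd > 0:
            keep = np.abs(nz - mu) <= 10 * sd
            n_out = int((~keep).sum())
            kept = nz[keep]
    if kept.size:
        q1, q2, q3 = np.percentile(kept, [25, 50, 75])
    else:
        q1 = q2 = q3 = 0.0

    grid = dens = None
    if kept.size >= 10:
        rng_width = kept.max() - kept.min()
        if rng_width > 0:
            bw = 0.1 * rng_width
            kde = stats.gaussian_kde(kept, bw_method=bw / kept.std(ddof=1))
            grid = np.linspace(kept.min() - bw, kept.max() + bw, density_points)
            dens = kde(grid)
    return DistributionSummary(
        mean_te=mean_te,
        n_significant=n_sig,
        n_values=int(te.size),
        quartiles=(float(q1), float(q2), float(q3)),
        n_outliers_excluded=n_out,
        density_grid=grid,
        density=dens,
    )


def lognormality_check(te_values: np.ndarray) -> tuple[float, float]:
    """Descriptive normality test on log nonzero TE values.

    Returns the D'Agostino-Pearson statistic and p-value for the
    hypothesis that log TE is Gaussian, i.e. that the nonzero TE values
    are log-normal.  Descriptive only: no downstream analysis branches
    on this result.
    """
    te = np.asarray(te_values, dtype=np.float64)
    nz = te[te > 0]
    if nz.size < 20:
        raise ValueError("need at least 20 positive values for the test")
    stat, p = stats.normaltest(np.log(nz))
    return float(stat), float(p)


def lockin_table(
    networks: dict[int, FunctionalNetwork],
    statistic: str = "edge",
    direction: str = "out",
) -> pd.DataFrame:
    """All early-late session pairs' lock-in correlations as a table.

    ``statistic`` is ``'edge'`` or ``'node'``; gated-out pairs appear
    with NaN correlation.  Days are taken from the dict keys and must be
    strictly increasing.
    """
    days = sorted(networks)
    rows = []
    for i, d0 in enumerate(days):
        for d1 in days[i + 1:]:
            try:
                if statistic == "edge":
                    rho, p, n = edge_lockin(networks[d0], networks[d1])
                else:
                    rho, p, n = node_flow_lockin(
                        networks[d0], networks[d1], direction
                    )
            except GateError:
                rho, p, n = np.nan, np.nan, 0
            rows.append(dict(day_early=d0, day_late=d1, rho=rho, p=p, n=n))
    return pd.DataFrame(rows)
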