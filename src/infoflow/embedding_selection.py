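"""Consensus embedding-length selection via AIS and TE maximisation.

One shared target history length ``l_x`` and source history length
``l_y`` are used for every node and pair of a study so that estimation
bias is comparable across nodes and sessions.  ``l_x`` is chosen by
increasing the length while the mean bias-corrected AIS across nodes
shows a statistically significant increase (paired two-sided t-test,
p < 0.05); ``l_y`` is chosen the same way with the mean
surrogate-mean-subtracted TE across all ordered pairs.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from infoflow.ct_estimators import EstimatorParams, estimate_ais_rate
from infoflow.significance import test_pair
from infoflow.spike_data import Recording

logger = logging.getLogger(__name__)

__all__ = ["select_target_embedding", "select_source_embedding"]


def _selection_scan(
    values_per_length: "callable",
    l_max: int,
    alpha: float,
    paired: bool,
) -> tuple[int, pd.DataFrame]:
    """Shared stopping rule: grow ``l`` while the mean statistic rises
    significantly; return the last accepted length and the trace table."""
    rows = []
    prev: np.ndarray | None = None
    selected = 1
    for l in range(1, l_max + 1):
        vals = np.asarray(values_per_length(l), dtype=np.float64)
        if prev is None:
            p_val = np.nan
            accepted = True
        else:
            if paired:
                t_stat, p_val = stats.ttest_rel(vals, prev)
            else:
                t_stat, p_val = stats.ttest_ind(vals, prev, equal_var=False)
            accepted = bool(p_val < alpha and vals.mean() > prev.mean())
        rows.append(
            dict(l=l, mean=vals.mean(), sd=vals.std(ddof=1), p_value=p_val,
                 accepted=accepted)
        )
        if not accepted:
            break
        selected = l
        prev = vals
    else:
        if l_max > 1 and rows[-1]["accepted"]:
            logger.warning(
                "statistic still increasing significantly at l_max=%d; "
                "returning l_max", l_max,
            )
    trace = pd.DataFrame(rows)
    return selected, trace


def select_target_embedding(
    recording: Recording,
    params: EstimatorParams | None = None,
    l_max: int = 8,
    alpha: float = 0.05,
    *,
    n_bias_surrogates: int = 20,
    paired: bool = True,
) -> tuple[int, pd.DataFrame]:
    """Select the consensus target history length ``l_x`` by AIS.

    Starting at ``l=1``, the length is increased while the increase in
    mean bias-corrected AIS across the recording's nodes is significant
    at ``alpha`` (paired two-sided t-test over nodes; Welch's unpaired
    test with ``paired=False``).  Returns the selected length and a trace
    table with one row per candidate (mean, SD, p, accepted).
    """
    params = params or EstimatorParams()
    if recording.n_nodes < 2:
        raise ValueError("need at least two nodes to select an embedding")

    def ais_at(l: int) -> list[float]:
        return [
            estimate_ais_rate(tr, l, params, n_bias_surrogates=n_bias_surrogates)
            for tr in recording
        ]

    return _selection_scan(ais_at, l_max, alpha, paired)


def select_source_embedding(
    recording: Recording,
    l_x: int,
    params: EstimatorParams | None = None,
    l_max: int = 8,
    alpha: float = 0.05,
    *,
    n_bias_surrogates: int = 20,
    paired: bool = True,
) -> tuple[int, pd.DataFrame]:
    """Select the consensus source history length ``l_y`` by mean TE.

    With ``l_x`` fixed, the statistic at each candidate ``l_y`` is the
    surrogate-mean-subtracted TE averaged over all ordered node pairs;
    the stopping rule is as in :func:`select_target_embedding`.
    """
    base = params or EstimatorParams()

    def te_at(l_y: int) -> list[float]:
        p = replace(base, l_x=l_x, l_y=l_y, n_surrogates=n_bias_surrogates)
        vals = []
        for src_id, tgt_id in permutations(recording.node_ids, 2):
            r, _ = test_pair(
                recording[src_id], recording[tgt_id], p, bias_correct=True
            )
            vals.append(r.te_rate)
        return vals

    return _selection_scan(te_at, l_max, alpha, paired)
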