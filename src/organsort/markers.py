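"""Marker-protein selection by replicate and cross-condition reproducibility.

Markers are proteins whose fractionation profile is both highly replicable
within each condition and stable between conditions; they supply the labeled
training data for localization.  Selection is a conjunctive four-stage filter
on a median-normalized quantification table:

1. normalization (assumed already applied);
2. the protein is quantified in both conditions;
3. the minimum pairwise Pearson correlation among its three replicate
   profiles (6 organelle values, per condition) is >= ``pcc_rep``;
4. the Pearson AND Spearman correlations between its replicate-mean profiles
   of the two conditions are >= ``pcc_cond`` and ``scc_cond``.

Correlations are computed over pairwise-complete (quantified in both
vectors) organelle entries; profiles with undefined correlations (zero
variance, or fewer than three shared entries) fail conservatively.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantio import QuantTable

logger = logging.getLogger(__name__)


@dataclass
class MarkerSelection:
    markers: list[str]
    records: pd.DataFrame  # per-protein filter statistics and passed_stage
    stage_counts: dict[int, int]  # proteins surviving through each stage


def _complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x, y = _complete(x, y)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan  # undefined -> conservative failure
    return float(np.corrcoef(x, y)[0, 1])


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    x, y = _complete(x, y)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(stats.spearmanr(x, y).statistic)


def select_markers(
    q: QuantTable,
    pcc_rep: float = 0.8,
    pcc_cond: float = 0.8,
    scc_cond: float = 0.6,
    stage3_scope: str = "per-condition",
) -> MarkerSelection:
    """Apply the four-stage marker filter.

    ``stage3_scope`` controls the replicate-correlation stage: the default
    computes pairwise replicate PCC within each condition over the 6 organelle
    values (both conditions must pass); ``"pooled"`` correlates pooled 12-dim
    replicate vectors instead.  Missing entries are excluded pairwise from
    the correlations, and condition-mean profiles average present replicate
    values.  Raising any threshold can only shrink the returned set (the
    filter is conjunctive).
    """
    conditions = q.conditions
    replicates = q.replicates
    if len(conditions) != 2:
        raise ValueError("marker selection requires exactly 2 conditions")
    if len(replicates) < 3:
        raise ValueError("marker selection requires >= 3 replicates")
    if stage3_scope not in ("per-condition", "pooled"):
        raise ValueError(f"unknown stage3_scope {stage3_scope!r}")
    organelles = q.organelles

    # per-protein 6-dim vector per (condition, replicate); missing kept NaN
    vecs: dict[tuple[str, int], np.ndarray] = {}
    present: dict[str, np.ndarray] = {}
    for cond in conditions:
        cols = [(o, cond, r) for r in replicates for o in organelles]
        block = q.data.loc[:, cols]
        present[cond] = block.notna().any(axis=1).to_numpy()
        for r in replicates:
            sub = q.data.loc[:, [(o, cond, r) for o in organelles]]
            vecs[(cond, r)] = sub.to_numpy()

    n = q.data.shape[0]
    pids = list(q.data.index)
    min_rep_pcc = {cond: np.full(n, np.nan) for cond in conditions}
    cross_pcc = np.full(n, np.nan)
    cross_scc = np.full(n, np.nan)
    passed_stage = np.zeros(n, dtype=int)

    both = present[conditions[0]] & present[conditions[1]]
    pairs = list(itertools.combinations(range(len(replicates)), 2))
    for i in range(n):
        passed_stage[i] = 1
        if not both[i]:
            continue
        passed_stage[i] = 2
        if stage3_scope == "per-condition":
            ok3 = True
            for cond in conditions:
                cc = [
                    _pearson(vecs[(cond, replicates[a])][i],
                             vecs[(cond, replicates[b])][i])
                    for a, b in pairs
                ]
                m = np.nan if np.any(np.isnan(cc)) else min(cc)
                min_rep_pcc[cond][i] = m
                if not (m >= pcc_rep):
                    ok3 = False
        else:
            pooled = {
                r: np.concatenate([vecs[(cond, r)][i] for cond in conditions])
                for r in replicates
            }
            cc = [_pearson(pooled[replicates[a]], pooled[replicates[b]])
                  for a, b in pairs]
            m = np.nan if np.any(np.isnan(cc)) else min(cc)
            for cond in conditions:
                min_rep_pcc[cond][i] = m
            ok3 = bool(m >= pcc_rep)
        if not ok3:
            continue
        passed_stage[i] = 3
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            mean_a = np.nanmean(
                [vecs[(conditions[0], r)][i] for r in replicates], axis=0
            )
            mean_b = np.nanmean(
                [vecs[(conditions[1], r)][i] for r in replicates], axis=0
            )
        cross_pcc[i] = _pearson(mean_a, mean_b)
        cross_scc[i] = _spearman(mean_a, mean_b)
        if cross_pcc[i] >= pcc_cond and cross_scc[i] >= scc_cond:
            passed_stage[i] = 4

    records = pd.DataFrame(
        {
            "protein_id": pids,
            "present_both_conditions": both,
            f"min_replicate_pcc_{conditions[0]}": min_rep_pcc[conditions[0]],
            f"min_replicate_pcc_{conditions[1]}": min_rep_pcc[conditions[1]],
            "cross_condition_pcc": cross_pcc,
            "cross_condition_scc": cross_scc,
            "passed_stage": passed_stage,
        }
    )
    stage_counts = {s: int((passed_stage >= s).sum()) for s in (1, 2, 3, 4)}
    logger.info("select_markers: retention by stage %s", stage_counts)
    markers = [pids[i] for i in np.flatnonzero(passed_stage == 4)]
    return MarkerSelection(markers=markers, records=records, stage_counts=stage_counts)
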