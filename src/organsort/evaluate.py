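"""Scoring of localization assignments against references or ground truth."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import UNCLASSIFIED, unique_argmax
from .cluster_annotate import COMPARTMENT_TO_NEIGHBORHOOD

logger = logging.getLogger(__name__)


@dataclass
class AgreementReport:
    n_overlap: int
    agreement: float | None
    per_neighborhood: pd.DataFrame
    per_stratum: pd.DataFrame | None = None


def map_reference_to_neighborhoods(
    ref: pd.DataFrame, mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Map a single-compartment reference table to neighborhood vocabulary.

    Uses the same fixed dictionary as cluster neighborhood definition;
    unmappable compartments are dropped with a log record.
    """
    mapping = COMPARTMENT_TO_NEIGHBORHOOD if mapping is None else mapping
    out = ref.copy()
    known = out["compartment"].isin(mapping)
    dropped = out.loc[~known, "compartment"].unique()
    if len(dropped):
        logger.info("map_reference_to_neighborhoods: dropped unmappable "
                    "compartments %s", sorted(dropped))
    out = out[known].copy()
    out["neighborhood"] = out["compartment"].map(mapping)
    return out[["protein_id", "neighborhood"] +
               [c for c in out.columns if c not in ("protein_id", "neighborhood",
                                                    "compartment")]]


def agreement(
    assignments: pd.DataFrame,
    ref: pd.DataFrame,
    stratify_by: str | None = None,
) -> AgreementReport:
    """Fraction of single-neighborhood-classified proteins whose call matches
    the (neighborhood-mapped) reference, overall, per neighborhood, and
    optionally per stratum of a reference column (e.g. a reliability grade)."""
    called = assignments[assignments["neighborhood"] != UNCLASSIFIED]
    merged = ref.merge(
        called["neighborhood"].rename("predicted"),
        left_on="protein_id", right_index=True,
    )
    n = len(merged)
    if n == 0:
        return AgreementReport(0, None, pd.DataFrame(
            columns=["neighborhood", "n", "agreement"]))
    merged["match"] = merged["neighborhood"] == merged["predicted"]
    per_nb = (
        merged.groupby("neighborhood")
        .agg(n=("match", "size"), agreement=("match", "mean"))
        .reset_index()
    )
    per_stratum = None
    if stratify_by is not None:
        per_stratum = (
            merged.groupby(stratify_by)
            .agg(n=("match", "size"), agreement=("match", "mean"))
            .reset_index()
        )
    return AgreementReport(
        n_overlap=n,
        agreement=float(merged["match"].mean()),
        per_neighborhood=per_nb,
        per_stratum=per_stratum,
    )


def marker_metrics(
    probabilities: pd.DataFrame,
    calls: pd.Series,
    true_labels: pd.Series,
) -> dict:
    """Pre- vs post-threshold accuracy and per-class precision/recall/F1 on
    labeled held-out markers.

    Pre-threshold calls are the unique argmax of the averaged probabilities;
    post-threshold calls are the final thresholded ``calls``.  Accuracies are
    computed over the respective retained (non-unclassified) subsets, with
    both denominators reported.  ``classified`` counts retained true-class
    markers; ``predicted`` counts those also correctly called.
    """
    common = probabilities.index.intersection(true_labels.index)
    probs, truth = probabilities.loc[common], true_labels.loc[common]
    pre_calls = unique_argmax(probs)
    post_calls = calls.reindex(common)
    post_calls = post_calls.where(post_calls != UNCLASSIFIED, pd.NA)

    def acc(c: pd.Series) -> tuple[float | None, int]:
        kept = c.dropna()
        if len(kept) == 0:
            return None, 0
        return float((kept == truth.loc[kept.index]).mean()), len(kept)

    pre_acc, pre_n = acc(pre_calls)
    post_acc, post_n = acc(post_calls)
    rows = []
    for cls in probs.columns:
        is_true = truth == cls
        pred = post_calls == cls
        tp = int((pred & is_true).sum())
        fp = int((pred & ~is_true).sum())
        fn = int((~pred & is_true).sum())
        precision = tp / (tp + fp) if tp + fp else np.nan
        recall = tp / (tp + fn) if tp + fn else np.nan
        f1 = (
            2 * precision * recall / (precision + recall)
            if tp + fp and tp + fn and precision + recall > 0
            else (0.0 if tp + fp and tp + fn else np.nan)
        )
        rows.append({
            "class": cls,
            "n_true": int(is_true.sum()),
            "classified": int((is_true & post_calls.notna()).sum()),
            "predicted": tp,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        })
    return {
        "accuracy_pre": pre_acc,
        "n_pre": pre_n,
        "accuracy_post": post_acc,
        "n_post": post_n,
        "per_class": pd.DataFrame(rows),
    }
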