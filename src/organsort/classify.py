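"""SVM localization with replicate merging and probability-threshold calibration.

One RBF-kernel SVM is trained per replicate on cluster-labeled marker
profiles, with (cost, gamma) chosen by 10-fold cross-validated accuracy over
log-spaced grids.  Per-protein class probabilities from the three replicates
are merged: the cluster call is kept only when at least two replicates agree
on the argmax, and the probability vectors are averaged.  Class-probability
cutoffs are then calibrated on held-out markers: for each class the threshold
maximizing recall subject to a precision floor (0.9 at the cluster level,
0.95 at the neighborhood level) is selected; when no threshold attains the
floor the F1-maximizing threshold is used instead.  Neighborhood
probabilities are sums of member-cluster probabilities, and cluster- and
neighborhood-level calls are reconciled: a cluster call whose neighborhood
disagrees with (or is missing from) the neighborhood-level call makes the
protein unclassified at both levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .quantio import ProfileMatrix

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


def _log_grid(lo: float, hi: float, num: int) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), num)


@dataclass
class SvmConfig:
    """RBF-SVM training configuration.

    Default grids span cost 1e-10..1e10 (11 log-spaced points) and gamma
    1e-10..10 (7 points); ``grid_preset="coarse"`` shrinks both for quick
    runs, ``"fine"`` doubles the resolution over the same ranges.
    Cross-validation accuracy ties are broken toward the least extreme
    (cost, gamma) pair.
    """

    cost_grid: np.ndarray = field(default_factory=lambda: _log_grid(1e-10, 1e10, 11))
    gamma_grid: np.ndarray = field(default_factory=lambda: _log_grid(1e-10, 10, 7))
    cv_folds: int = 10
    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    adapt_folds: bool = False  # lower folds to smallest class when needed

    def __post_init__(self) -> None:
        if len(self.cost_grid) == 0 or len(self.gamma_grid) == 0:
            raise ValueError("grids must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    @classmethod
    def preset(cls, name: str, **kw) -> "SvmConfig":
        if name == "paper":
            return cls(**kw)
        if name == "fine":
            return cls(
                cost_grid=_log_grid(1e-10, 1e10, 21),
                gamma_grid=_log_grid(1e-10, 10, 12),
                **kw,
            )
        if name == "coarse":
            return cls(
                cost_grid=_log_grid(1e-4, 1e4, 5),
                gamma_grid=_log_grid(1e-4, 10, 4),
                **kw,
            )
        raise ValueError(f"unknown grid preset {name!r}")


def split_markers(
    labels: pd.Series, cfg: SvmConfig
) -> tuple[pd.Index, pd.Index]:
    """Stratified train/test split of cluster-labeled markers (disjoint,
    exhaustive, seeded).  Errors when a cluster has fewer than 3 markers."""
    counts = labels.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(
            f"clusters with fewer than 3 markers: {sorted(small.index.tolist())}; "
            "merge these clusters or drop them before splitting"
        )
    train_idx, test_idx = train_test_split(
        labels.index,
        train_size=cfg.train_fraction,
        stratify=labels.to_numpy(),
        random_state=cfg.seed,
    )
    return pd.Index(train_idx), pd.Index(test_idx)


def _ordered_param_candidates(cfg: SvmConfig) -> list[dict]:
    """Grid candidates sorted least-extreme-first so CV-accuracy ties resolve
    to moderate hyperparameters (the grid search keeps the first best)."""
    cands = [
        {"C": [c], "gamma": [g]} for c in cfg.cost_grid for g in cfg.gamma_grid
    ]
    return sorted(
        cands,
        key=lambda d: abs(np.log10(d["C"][0])) + abs(np.log10(d["gamma"][0])),
    )


def train_predict(
    profiles: ProfileMatrix,
    train_labels: pd.Series,
    cfg: SvmConfig,
) -> dict[int, pd.DataFrame]:
    """Per replicate: grid-searched RBF-SVM fit on training markers, class
    probabilities for every protein with a usable profile in that replicate.

    Probabilities come from the SVM's pairwise-coupling (Platt) model.
    """
    if train_labels.nunique() < 2:
        raise ValueError("training data must contain >= 2 classes")
    replicates = sorted(profiles.values.index.get_level_values("replicate").unique())
    classes = sorted(train_labels.unique())
    out: dict[int, pd.DataFrame] = {}
    for rep in replicates:
        block = profiles.values.xs(rep, level="replicate")
        ok = ~profiles.flagged.xs(rep, level="replicate")
        block = block[ok]
        train_ids = train_labels.index.intersection(block.index)
        X = block.loc[train_ids].to_numpy()
        y = train_labels.loc[train_ids].to_numpy()
        folds = cfg.cv_folds
        min_class = int(pd.Series(y).value_counts().min())
        if min_class < folds:
            if not cfg.adapt_folds:
                raise ValueError(
                    f"replicate {rep}: smallest training class has {min_class} "
                    f"markers < {folds} folds; merge clusters or reduce folds"
                )
            folds = max(2, min_class)
            logger.warning("replicate %s: folds reduced to %d", rep, folds)
        gs = GridSearchCV(
            SVC(kernel="rbf"),
            _ordered_param_candidates(cfg),
            cv=StratifiedKFold(folds, shuffle=True, random_state=cfg.seed),
            n_jobs=1,
        )
        gs.fit(X, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model = SVC(
                kernel="rbf", probability=True, random_state=cfg.seed,
                **gs.best_params_,
            )
            model.fit(X, y)
        proba = model.predict_proba(block.to_numpy())
        frame = pd.DataFrame(proba, index=block.index, columns=model.classes_)
        frame = frame.reindex(columns=classes, fill_value=0.0)
        frame.attrs["best_params"] = dict(gs.best_params_)
        frame.attrs["cv_accuracy"] = float(gs.best_score_)
        logger.info(
            "train_predict: replicate %s best %s (CV acc %.3f)",
            rep, gs.best_params_, gs.best_score_,
        )
        out[rep] = frame
    return out


@dataclass
class MergedPrediction:
    """Replicate-merged predictions: modal calls and averaged probabilities."""

    calls: pd.Series        # protein_id -> modal cluster or NA
    probabilities: pd.DataFrame  # protein_id x cluster, averaged
    consistency: pd.Series  # protein_id -> number of agreeing replicates


def merge_replicates(per_replicate: dict[int, pd.DataFrame]) -> MergedPrediction:
    """Keep the modal argmax cluster when >= 2 replicates agree; average the
    probability vectors over the replicates in which the protein was scored.
    Proteins scored in fewer than 2 replicates are unclassified."""
    if len(per_replicate) < 2:
        raise ValueError("need >= 2 replicate probability matrices")
    classes = next(iter(per_replicate.values())).columns
    all_ids = pd.Index([])
    for frame in per_replicate.values():
        all_ids = all_ids.union(frame.index)
    argmaxes = pd.DataFrame(index=all_ids, columns=sorted(per_replicate), dtype=object)
    for rep, frame in per_replicate.items():
        argmaxes.loc[frame.index, rep] = frame.idxmax(axis=1)
    stack = pd.concat(per_replicate.values())
    avg = stack.groupby(level=0).mean().reindex(all_ids)
    avg = avg.div(avg.sum(axis=1), axis=0)

    calls, consistency = {}, {}
    for pid in all_ids:
        votes = argmaxes.loc[pid].dropna()
        if len(votes) < 2:
            calls[pid] = pd.NA
            consistency[pid] = 0
            continue
        top = votes.value_counts()
        if top.iloc[0] >= 2:
            calls[pid] = top.index[0]
            consistency[pid] = int(top.iloc[0])
        else:
            calls[pid] = pd.NA  # all replicates disagree
            consistency[pid] = 1
    n_uncl = sum(pd.isna(v) for v in calls.values())
    logger.info("merge_replicates: %d/%d proteins unclassified by replicate "
                "consistency", n_uncl, len(all_ids))
    return MergedPrediction(
        calls=pd.Series(calls, name="cluster"),
        probabilities=avg[classes],
        consistency=pd.Series(consistency, name="consistency"),
    )


def unique_argmax(probabilities: pd.DataFrame) -> pd.Series:
    """Per-protein class with strictly maximal probability (ties -> NA)."""
    arr = probabilities.to_numpy()
    order = np.argsort(arr, axis=1)
    top, second = arr[np.arange(len(arr)), order[:, -1]], (
        arr[np.arange(len(arr)), order[:, -2]] if arr.shape[1] > 1 else
        np.full(len(arr), -np.inf)
    )
    out = pd.Series(
        [probabilities.columns[i] for i in order[:, -1]],
        index=probabilities.index, dtype=object,
    )
    out[top <= second] = pd.NA
    return out


@dataclass
class PRPoint:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def pr_curve(
    scores: np.ndarray, is_argmax: np.ndarray, is_true: np.ndarray,
    thresholds: np.ndarray,
) -> list[PRPoint]:
    """One-vs-rest PR points; a protein is predicted for the class when the
    class is its (unique) argmax AND its score reaches the threshold."""
    points = []
    for t in thresholds:
        pred = is_argmax & (scores >= t)
        tp = int(np.sum(pred & is_true))
        fp = int(np.sum(pred & ~is_true))
        fn = int(np.sum(~pred & is_true))
        tn = int(np.sum(~pred & ~is_true))
        points.append(PRPoint(threshold=float(t), tp=tp, fp=fp, tn=tn, fn=fn))
    return points


def calibrate_class_threshold(
    scores: np.ndarray,
    is_argmax: np.ndarray,
    is_true: np.ndarray,
    precision_floor: float,
) -> tuple[float, str, PRPoint]:
    """Select the class-probability cutoff on held-out markers.

    Candidate thresholds are the observed score values plus 0 and 1 (PR
    curves are step functions, so this search is exact).  Among thresholds
    reaching the precision floor the one maximizing recall wins (ties: higher
    precision, then lower threshold); if the floor is unattainable the
    F1-maximizing threshold is used and the mode recorded as ``"F1-max"``.
    A class whose best achievable F1 is zero (no threshold yields a single
    true positive) has no usable operating point: it is closed (mode
    ``"closed"``, threshold NaN) and emits only unclassified.
    """
    thresholds = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    points = pr_curve(scores, is_argmax, is_true, thresholds)
    feasible = [pt for pt in points if pt.tp + pt.fp > 0
                and pt.precision >= precision_floor]
    if feasible:
        best = max(feasible, key=lambda pt: (pt.recall, pt.precision, -pt.threshold))
        return best.threshold, "precision-floor", best
    best = max(points, key=lambda pt: (pt.f1, pt.precision, -pt.threshold))
    if best.f1 == 0.0:
        return float("nan"), "closed", best
    return best.threshold, "F1-max", best


def calibrate_thresholds(
    probabilities: pd.DataFrame,
    true_labels: pd.Series,
    level: str,
    precision_floor: float,
) -> pd.DataFrame:
    """Per-class threshold table from held-out predictions and true labels.

    Classes absent from the test set get no threshold (they will emit only
    unclassified).  Returns columns: level, class, threshold, mode,
    precision, recall, f1, n_true.
    """
    common = probabilities.index.intersection(true_labels.index)
    probs = probabilities.loc[common]
    truth = true_labels.loc[common]
    amax = unique_argmax(probs)
    rows = []
    for cls in probs.columns:
        is_true = (truth == cls).to_numpy()
        if not is_true.any():
            logger.warning("calibrate_thresholds: class %s absent from the "
                           "test set; no threshold", cls)
            rows.append((level, cls, np.nan, "absent", np.nan, np.nan, np.nan, 0))
            continue
        scores = probs[cls].to_numpy()
        is_am = (amax == cls).to_numpy()
        t, mode, pt = calibrate_class_threshold(
            scores, is_am, is_true, precision_floor
        )
        rows.append((level, cls, t, mode, pt.precision, pt.recall, pt.f1,
                     int(is_true.sum())))
    return pd.DataFrame(
        rows,
        columns=["level", "class", "threshold", "mode", "precision", "recall",
                 "f1", "n_true"],
    )


def apply_thresholds(
    probabilities: pd.DataFrame, thresholds: pd.DataFrame,
    eligible: pd.Series | None = None,
) -> pd.Series:
    """Final calls: the unique-argmax class when its averaged probability
    reaches that class's threshold, else unclassified.  ``eligible`` can
    restrict calls (e.g. to proteins passing replicate consistency)."""
    tmap = thresholds.set_index("class")["threshold"].to_dict()
    amax = unique_argmax(probabilities)
    calls = {}
    for pid in probabilities.index:
        cls = amax.loc[pid]
        if pd.isna(cls):
            calls[pid] = pd.NA
            continue
        if eligible is not None and not bool(eligible.get(pid, True)):
            calls[pid] = pd.NA
            continue
        t = tmap.get(cls, np.nan)
        if np.isnan(t) or probabilities.loc[pid, cls] < t:
            calls[pid] = pd.NA
        else:
            calls[pid] = cls
    return pd.Series(calls, name="call")


def aggregate_neighborhood(
    probabilities: pd.DataFrame, neighborhood_map: dict
) -> pd.DataFrame:
    """Sum member-cluster probabilities into neighborhood probabilities
    (probability mass is conserved)."""
    missing = [c for c in probabilities.columns if c not in neighborhood_map]
    if missing:
        raise ValueError(f"clusters without a neighborhood: {missing}")
    groups: dict[str, list] = {}
    for cluster, nb in neighborhood_map.items():
        if cluster in probabilities.columns:
            groups.setdefault(nb, []).append(cluster)
    out = pd.DataFrame(
        {nb: probabilities[cols].sum(axis=1) for nb, cols in sorted(groups.items())},
        index=probabilities.index,
    )
    return out


def reconcile_levels(
    cluster_calls: pd.Series,
    neighborhood_calls: pd.Series,
    neighborhood_map: dict,
    cluster_probs: pd.DataFrame | None = None,
    neighborhood_probs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge cluster- and neighborhood-level calls into final assignments.

    A protein with a cluster call whose mapped neighborhood differs from its
    neighborhood call — or that has no neighborhood call at all — becomes
    unclassified at both levels.  A protein without a cluster call keeps a
    neighborhood-only call (rescue semantics).
    """
    ids = cluster_calls.index.union(neighborhood_calls.index)
    rows = []
    n_reconciled = 0
    for pid in ids:
        c = cluster_calls.get(pid, pd.NA)
        nb = neighborhood_calls.get(pid, pd.NA)
        if not pd.isna(c):
            mapped = neighborhood_map[c]
            if pd.isna(nb) or nb != mapped:
                c, nb = pd.NA, pd.NA
                n_reconciled += 1
        cp = (
            float(cluster_probs.loc[pid].max())
            if cluster_probs is not None and pid in cluster_probs.index
            else np.nan
        )
        nbp = (
            float(neighborhood_probs.loc[pid].max())
            if neighborhood_probs is not None and pid in neighborhood_probs.index
            else np.nan
        )
        rows.append((pid, c if not pd.isna(c) else UNCLASSIFIED,
                     nb if not pd.isna(nb) else UNCLASSIFIED, cp, nbp))
    logger.info("reconcile_levels: %d proteins reconciled to unclassified",
                n_reconciled)
    out = pd.DataFrame(
        rows,
        columns=["protein_id", "cluster", "neighborhood",
                 "cluster_probability", "neighborhood_probability"],
    ).set_index("protein_id")
    out.attrs["n_reconciled"] = n_reconciled
    return out


def export_network(assignments: pd.DataFrame, neighborhood_map: dict):
    """Protein→cluster→neighborhood hierarchy as node/edge tables + graph.

    Proteins with a cluster call attach to their cluster; proteins with only
    a neighborhood call attach directly to the neighborhood.  Returns
    (nodes DataFrame, edges DataFrame, networkx.DiGraph) — the graph can be
    written with ``networkx.write_graphml``.
    """
    import networkx as nx

    g = nx.DiGraph()
    nodes, edges = [], []
    for nb in sorted(set(neighborhood_map.values())):
        g.add_node(f"neighborhood:{nb}", kind="neighborhood", label=str(nb))
        nodes.append((f"neighborhood:{nb}", "neighborhood", str(nb)))
    for cluster, nb in sorted(neighborhood_map.items(), key=lambda kv: str(kv[0])):
        cid = f"cluster:{cluster}"
        g.add_node(cid, kind="cluster", label=str(cluster))
        nodes.append((cid, "cluster", str(cluster)))
        g.add_edge(cid, f"neighborhood:{nb}")
        edges.append((cid, f"neighborhood:{nb}", "cluster-neighborhood"))
    for pid, row in assignments.iterrows():
        if row["cluster"] != UNCLASSIFIED:
            target = f"cluster:{row['cluster']}"
        elif row["neighborhood"] != UNCLASSIFIED:
            target = f"neighborhood:{row['neighborhood']}"
        else:
            continue
        g.add_node(str(pid), kind="protein", label=str(pid))
        nodes.append((str(pid), "protein", str(pid)))
        g.add_edge(str(pid), target)
        edges.append((str(pid), target, "assignment"))
    return (
        pd.DataFrame(nodes, columns=["id", "kind", "label"]),
        pd.DataFrame(edges, columns=["source", "target", "kind"]),
        g,
    )
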