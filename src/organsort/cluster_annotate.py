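"""Cluster discovery and compartment annotation of marker proteins.

Replicate-averaged marker profiles are embedded into three dimensions with
t-SNE, clusters are discovered by fitting Gaussian mixtures over a range of
component counts and selecting the count with the best BIC, and each cluster
is annotated with subcellular compartments by hypergeometric enrichment of
reference annotations under five annotation strategies with a 3-of-5
consistency vote.  Annotated compartments are finally collapsed to five
neighborhoods (secretory, mitochondria, nuclear, cytosol, ribosome) through a
fixed compartment→neighborhood dictionary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Fixed compartment -> neighborhood dictionary (11-compartment vocabulary).
COMPARTMENT_TO_NEIGHBORHOOD = {
    "endoplasmic reticulum": "secretory",
    "Golgi apparatus": "secretory",
    "endosome": "secretory",
    "lysosome": "secretory",
    "plasma membrane": "secretory",
    "peroxisome": "secretory",
    "mitochondrion": "mitochondria",
    "nucleus": "nuclear",
    "cytosol": "cytosol",
    "cytoskeleton": "cytosol",
    "ribosome": "ribosome",
}

STRATEGIES = ("uniprot_only", "go_only", "union", "intersection", "union_and_mouse")


@dataclass
class TsneConfig:
    perplexity: float = 50.0
    theta: float = 0.5
    output_dims: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")


@dataclass
class Embedding:
    coords: pd.DataFrame  # protein_id x (dim1..dim3)
    config: TsneConfig


@dataclass
class ClusterModel:
    k: int
    labels: pd.Series               # protein_id -> cluster id (1-based)
    memberships: pd.DataFrame       # protein_id x cluster posterior
    bic: dict[int, float]
    means: np.ndarray
    covariances: np.ndarray


@dataclass
class EnrichmentResult:
    b: int
    n: int
    B: int
    N: int
    fc: float
    p: float


@dataclass
class ClusterAnnotation:
    """Per-cluster compartment assignments with per-strategy verdicts."""

    assignments: dict[int, set[str]]
    strategy_tables: dict[str, pd.DataFrame]
    votes: pd.DataFrame  # (cluster, compartment) -> votes among 5 strategies


def embed_tsne(mean_profiles: pd.DataFrame, cfg: TsneConfig) -> Embedding:
    """3-D t-SNE of replicate-averaged marker profiles (seed-deterministic).

    ``theta`` is the Barnes-Hut speed/accuracy trade-off; ``perplexity``
    roughly the expected cluster size.  Requires > 3*perplexity markers.
    """
    n = mean_profiles.shape[0]
    if n - 1 < 3 * cfg.perplexity:
        raise ValueError(
            f"too few markers ({n}) for perplexity {cfg.perplexity}: "
            "need n - 1 >= 3 * perplexity"
        )
    tsne = TSNE(
        n_components=cfg.output_dims,
        perplexity=cfg.perplexity,
        angle=cfg.theta,
        method="barnes_hut",
        init="pca",
        random_state=cfg.seed,
        n_jobs=1,
    )
    coords = tsne.fit_transform(mean_profiles.to_numpy())
    frame = pd.DataFrame(
        coords,
        index=mean_profiles.index,
        columns=[f"dim{i + 1}" for i in range(cfg.output_dims)],
    )
    return Embedding(coords=frame, config=cfg)


def fit_gmm_bic(
    embedding: Embedding,
    k_candidates: range | list[int] = range(1, 26),
    seed: int = 0,
    n_init: int = 5,
    reg_covar: float = 1e-6,
) -> ClusterModel:
    """EM mixture-of-Gaussians fits over candidate component counts; the count
    with the lowest BIC wins (ties break toward fewer components).

    Each candidate uses ``n_init`` k-means-seeded restarts on a fixed seed
    schedule; degenerate covariances are handled by the ``reg_covar`` ridge.
    """
    ks = sorted(set(int(k) for k in k_candidates))
    if not ks:
        raise ValueError("empty candidate range")
    X = embedding.coords.to_numpy()
    if max(ks) >= X.shape[0]:
        raise ValueError("max candidate k must be < number of points")
    bic: dict[int, float] = {}
    models: dict[int, GaussianMixture] = {}
    for k in ks:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            reg_covar=reg_covar,
            random_state=seed,
        )
        gm.fit(X)
        bic[k] = float(gm.bic(X))
        models[k] = gm
    best_k = min(ks, key=lambda k: (bic[k], k))
    gm = models[best_k]
    resp = gm.predict_proba(X)
    labels = pd.Series(
        resp.argmax(axis=1) + 1, index=embedding.coords.index, name="cluster"
    )
    memberships = pd.DataFrame(
        resp, index=embedding.coords.index, columns=range(1, best_k + 1)
    )
    logger.info("fit_gmm_bic: selected k=%d (BIC %.1f)", best_k, bic[best_k])
    return ClusterModel(
        k=best_k,
        labels=labels,
        memberships=memberships,
        bic=bic,
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
    )


def enrichment_test(b: int, n: int, B: int, N: int) -> EnrichmentResult:
    """Fold change (b/n)/(B/N) and upper-tail hypergeometric P(X >= b) for
    drawing ``n`` proteins from ``N`` of which ``B`` carry the target label."""
    if not (0 <= b <= min(n, B) and n <= N and B <= N):
        raise ValueError(f"inconsistent counts b={b}, n={n}, B={B}, N={N}")
    if B == 0 or n == 0:
        raise ValueError("fold change undefined for B=0 or n=0")
    fc = (b / n) / (B / N)
    p = float(stats.hypergeom.sf(b - 1, N, B, n))
    return EnrichmentResult(b=b, n=n, B=B, N=N, fc=fc, p=min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _strategy_labels(
    refs: dict[str, pd.DataFrame], strategy: str
) -> pd.Series:
    """Protein -> compartment labels used by one annotation strategy.

    Sources are single-localization tables; "exclusively annotated in a
    source" is read as single-location in that source.  Where two sources are
    combined and disagree on a protein, the protein is dropped from that
    strategy (its label is ambiguous).
    """
    def series(name: str) -> pd.Series:
        df = refs[name]
        return pd.Series(df["compartment"].values, index=df["protein_id"].values)

    up, go = series("uniprot"), series("go")
    if strategy == "uniprot_only":
        return up
    if strategy == "go_only":
        return go
    both = up.index.intersection(go.index)
    agree = both[(up.loc[both] == go.loc[both]).values]
    if strategy == "intersection":
        return up.loc[agree]
    union = pd.concat([up, go.loc[go.index.difference(up.index)]])
    union = union.drop(both.difference(agree))  # conflicting labels dropped
    if strategy == "union":
        return union
    if strategy == "union_and_mouse":
        mouse = series("mouse")
        keep = union.index.intersection(mouse.index)
        keep = keep[(union.loc[keep] == mouse.loc[keep]).values]
        return union.loc[keep]
    raise ValueError(f"unknown strategy {strategy!r}")


def annotate_clusters(
    labels: pd.Series,
    refs: dict[str, pd.DataFrame],
    fc_min: float = 2.0,
    q_max: float = 0.05,
    min_votes: int = 3,
    compartments: tuple[str, ...] | None = None,
) -> ClusterAnnotation:
    """Annotate each cluster with enriched compartments by 3-of-5 voting.

    Per strategy, every (cluster, compartment) pair is tested for enrichment
    of the strategy's annotated markers (fold change >= ``fc_min``, inclusive,
    and BH-adjusted significance < ``q_max``, strict); BH correction is
    applied within each strategy across all its tests.  A compartment is
    assigned to a cluster when at least ``min_votes`` of the five strategies
    agree; a strategy with no annotated markers is skipped but still counts
    in the denominator.
    """
    clusters = sorted(labels.unique())
    strategy_tables: dict[str, pd.DataFrame] = {}
    vote_counts: dict[tuple[int, str], int] = {}
    for strategy in STRATEGIES:
        ann = _strategy_labels(refs, strategy)
        ann = ann.loc[ann.index.intersection(labels.index)]
        if len(ann) == 0:
            logger.warning("annotate_clusters: strategy %s has no annotated markers; "
                           "skipped (denominator unchanged)", strategy)
            strategy_tables[strategy] = pd.DataFrame(
                columns=["cluster", "compartment", "b", "n", "B", "N", "fc", "p", "q"]
            )
            continue
        comps = (
            list(compartments)
            if compartments is not None
            else sorted(ann.unique())
        )
        N = len(ann)
        rows = []
        for c in clusters:
            in_c = ann.loc[labels.index[labels == c].intersection(ann.index)]
            n = len(in_c)
            for comp in comps:
                B = int((ann == comp).sum())
                if B == 0 or n == 0:
                    continue
                b = int((in_c == comp).sum())
                r = enrichment_test(b, n, B, N)
                rows.append((c, comp, r.b, r.n, r.B, r.N, r.fc, r.p))
        table = pd.DataFrame(
            rows, columns=["cluster", "compartment", "b", "n", "B", "N", "fc", "p"]
        )
        table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
        strategy_tables[strategy] = table
        hits = table[(table["fc"] >= fc_min) & (table["q"] < q_max)]
        for _, row in hits.iterrows():
            key = (int(row["cluster"]), str(row["compartment"]))
            vote_counts[key] = vote_counts.get(key, 0) + 1

    votes = pd.DataFrame(
        [(c, comp, v) for (c, comp), v in sorted(vote_counts.items())],
        columns=["cluster", "compartment", "votes"],
    )
    assignments: dict[int, set[str]] = {int(c): set() for c in clusters}
    for (c, comp), v in vote_counts.items():
        if v >= min_votes:
            assignments[c].add(comp)
    logger.info(
        "annotate_clusters: %d/%d clusters annotated",
        sum(bool(s) for s in assignments.values()), len(clusters),
    )
    return ClusterAnnotation(
        assignments=assignments, strategy_tables=strategy_tables, votes=votes
    )


def second_round_annotation(
    labels: pd.Series, term_table: pd.DataFrame, fc_min: float = 2.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Supplementary target-vs-background term enrichment per cluster.

    ``term_table`` maps protein_id -> term (one row per pair); each cluster is
    the target set and all labeled markers the background, reusing the same
    hypergeometric machinery.  Results are supplementary annotations and do
    not feed the neighborhood map.
    """
    terms = term_table[term_table["protein_id"].isin(labels.index)]
    N = terms["protein_id"].nunique()
    rows = []
    for c in sorted(labels.unique()):
        members = set(labels.index[labels == c])
        in_c = terms[terms["protein_id"].isin(members)]
        n = in_c["protein_id"].nunique()
        if n == 0:
            continue
        for term, grp in terms.groupby(terms.columns[1]):
            B = grp["protein_id"].nunique()
            b = in_c[in_c[in_c.columns[1]] == term]["protein_id"].nunique()
            if B == 0:
                continue
            r = enrichment_test(b, n, B, N)
            rows.append((c, term, r.b, r.n, r.B, r.N, r.fc, r.p))
    out = pd.DataFrame(
        rows, columns=["cluster", "term", "b", "n", "B", "N", "fc", "p"]
    )
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["enriched"] = (out["fc"] >= fc_min) & (out["q"] < q_max) if len(out) else []
    return out


def define_neighborhoods(
    assignments: dict[int, set[str]],
    mapping: dict[str, str] | None = None,
    overrides: dict[int, str] | None = None,
) -> dict[int, str]:
    """Collapse per-cluster compartment sets to a single neighborhood each.

    Unannotated clusters must be named in ``overrides``; a cluster whose
    compartments span two or more neighborhoods is an error (the conflict is
    listed) unless an override resolves it.
    """
    mapping = COMPARTMENT_TO_NEIGHBORHOOD if mapping is None else mapping
    overrides = overrides or {}
    out: dict[int, str] = {}
    conflicts, unmapped = [], []
    for cluster, comps in sorted(assignments.items()):
        if cluster in overrides:
            out[cluster] = overrides[cluster]
            continue
        unknown = [c for c in comps if c not in mapping]
        if unknown:
            raise ValueError(f"cluster {cluster}: unknown compartments {unknown}")
        nbs = {mapping[c] for c in comps}
        if len(nbs) == 0:
            unmapped.append(cluster)
        elif len(nbs) > 1:
            conflicts.append((cluster, sorted(nbs)))
        else:
            out[cluster] = nbs.pop()
    if conflicts:
        raise ValueError(
            "clusters with compartments spanning multiple neighborhoods: "
            + "; ".join(f"cluster {c} -> {nbs}" for c, nbs in conflicts)
        )
    if unmapped:
        raise ValueError(
            f"unannotated clusters {unmapped} require an explicit mapping"
        )
    return out
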