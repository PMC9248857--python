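"""End-to-end orchestration: simulate/load → normalize → markers → cluster →
annotate → classify → evaluate → domains/complexes, with one config, one seed
and a reproducibility manifest.

The pipeline is deterministic under a fixed config: every stochastic stage is
seeded from the global seed, and two runs with the same config produce
byte-identical output tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synthetic_data import GeneratorConfig, SimulatedExperiment, simulate_experiment
from .quantio import (
    QuantTable, build_profiles, median_normalize, quant_table_from_frame,
    read_quant_table,
)
from .markers import MarkerSelection, select_markers
from .cluster_annotate import (
    COMPARTMENT_TO_NEIGHBORHOOD, ClusterAnnotation, ClusterModel, Embedding,
    TsneConfig, annotate_clusters, define_neighborhoods, embed_tsne, fit_gmm_bic,
)
from .classify import (
    MergedPrediction, SvmConfig, UNCLASSIFIED, aggregate_neighborhood,
    apply_thresholds, calibrate_thresholds, export_network, merge_replicates,
    reconcile_levels, split_markers, train_predict,
)
from .evaluate import agreement, map_reference_to_neighborhoods, marker_metrics
from .domains_complexes import (
    complex_colocalization, complex_member_correlations, domain_enrichment,
    random_pair_null,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the published procedure
    (perplexity 50, theta 0.5, PCC 0.8, SCC 0.6, FC 2, q 0.05, precision
    floors 0.9/0.95, 10-fold CV)."""

    seed: int = 0
    simulate: GeneratorConfig | None = None
    quant_path: str | None = None
    reference_paths: dict[str, str] = field(default_factory=dict)
    domain_path: str | None = None
    complex_path: str | None = None
    # markers
    pcc_rep: float = 0.8
    pcc_cond: float = 0.8
    scc_cond: float = 0.6
    # clustering / annotation
    perplexity: float = 50.0
    theta: float = 0.5
    kmin: int = 1
    kmax: int = 25
    gmm_restarts: int = 5
    fc_min: float = 2.0
    q_max: float = 0.05
    min_votes: int = 3
    # classification
    grid_preset: str = "paper"
    cv_folds: int = 10
    train_fraction: float = 2.0 / 3.0
    precision_floor_cluster: float = 0.9
    precision_floor_neighborhood: float = 0.95
    min_markers_per_cluster: int = 3
    # domains / complexes
    domain_log2fc_cutoff: float = 2.0
    domain_q_cutoff: float = 0.05
    domain_min_occurrence: int = 3
    complex_pcc_cutoff: float = 0.8
    null_pairs: int = 2000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim is not None:
            if "neighborhood_map" in sim:
                sim["neighborhood_map"] = {
                    int(k): v for k, v in sim["neighborhood_map"].items()
                }
            for key in ("organelles", "conditions"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulate = GeneratorConfig(**sim)
        if cfg.simulate is None and cfg.quant_path is None:
            raise ValueError("config must set either 'simulate' or 'quant_path'")
        return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    experiment: SimulatedExperiment | None
    normalized: QuantTable
    marker_selection: MarkerSelection
    embedding: Embedding
    cluster_model: ClusterModel
    annotation: ClusterAnnotation
    neighborhood_map: dict
    neighborhood_overrides: dict
    train_ids: pd.Index
    test_ids: pd.Index
    merged: MergedPrediction
    cluster_thresholds: pd.DataFrame
    neighborhood_thresholds: pd.DataFrame
    neighborhood_probs: pd.DataFrame
    assignments: pd.DataFrame
    metrics_cluster: dict
    metrics_neighborhood: dict
    agreement_reports: dict
    domain_table: pd.DataFrame | None
    complex_results: list | None
    null_result: dict | None
    manifest: dict


def _stage(name: str):
    def wrap(fn):
        def inner(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def _resolve_neighborhoods(
    annotation: ClusterAnnotation,
    labels: pd.Series,
    refs: dict[str, pd.DataFrame],
) -> tuple[dict, dict, list]:
    """Strict neighborhood definition with a logged majority-vote fallback.

    Clusters that are unannotated or whose compartments span neighborhoods
    get the majority neighborhood of their members' union annotations; a
    cluster with no annotated member at all cannot be placed and is dropped
    from classification (returned in the third element).
    """
    from .cluster_annotate import _strategy_labels

    try:
        return define_neighborhoods(annotation.assignments), {}, []
    except ValueError:
        pass
    union = _strategy_labels(refs, "union")
    union_nb = union.map(COMPARTMENT_TO_NEIGHBORHOOD).dropna()
    overrides: dict[int, str] = {}
    dropped: list[int] = []
    for cluster, comps in annotation.assignments.items():
        nbs = {COMPARTMENT_TO_NEIGHBORHOOD[c] for c in comps
               if c in COMPARTMENT_TO_NEIGHBORHOOD}
        if len(nbs) == 1:
            continue
        members = labels.index[labels == cluster]
        ann = union_nb.loc[union_nb.index.intersection(members)]
        if len(ann) == 0:
            dropped.append(cluster)
            logger.warning(
                "neighborhoods: cluster %s has no annotated members; dropped "
                "from classification", cluster,
            )
            continue
        overrides[cluster] = ann.value_counts().index[0]
        logger.warning(
            "neighborhoods: cluster %s resolved by member majority -> %s",
            cluster, overrides[cluster],
        )
    kept = {c: s for c, s in annotation.assignments.items() if c not in dropped}
    if not kept:
        raise ValueError("no cluster could be placed in a neighborhood")
    return define_neighborhoods(kept, overrides=overrides), overrides, dropped


def run_all(cfg: PipelineConfig, outdir=None) -> PipelineResult:
    """Run every stage in order and (optionally) write all outputs."""
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in asdict(cfg).items()
            if k not in ("simulate", "reference_paths")
        },
        "counts": {},
    }
    counts = manifest["counts"]

    # ------------------------------------------------------------ inputs
    @_stage("simulate")
    def load() -> tuple[QuantTable, dict, SimulatedExperiment | None,
                        pd.DataFrame | None, pd.DataFrame | None]:
        if cfg.simulate is not None:
            exp = simulate_experiment(cfg.simulate)
            manifest["generator_config"] = {
                **{k: v for k, v in asdict(cfg.simulate).items()
                   if k != "neighborhood_map"},
            }
            return (
                quant_table_from_frame(exp.quant), exp.references, exp,
                exp.domains, exp.complexes,
            )
        q = read_quant_table(cfg.quant_path)
        refs = {
            name: pd.read_csv(path, sep="\t")
            for name, path in cfg.reference_paths.items()
        }
        doms = (
            pd.read_csv(cfg.domain_path, sep="\t") if cfg.domain_path else None
        )
        cplx = (
            pd.read_csv(cfg.complex_path, sep="\t") if cfg.complex_path else None
        )
        return q, refs, None, doms, cplx

    quant, refs, experiment, domains, complexes = load()
    counts["proteins"] = int(quant.data.shape[0])

    # ---------------------------------------------------------- normalize
    normalized = _stage("normalize")(median_normalize)(quant)

    # ------------------------------------------------------------ markers
    @_stage("markers")
    def stage_markers() -> MarkerSelection:
        return select_markers(
            normalized, pcc_rep=cfg.pcc_rep, pcc_cond=cfg.pcc_cond,
            scc_cond=cfg.scc_cond,
        )

    selection = stage_markers()
    counts["markers_by_stage"] = selection.stage_counts
    counts["markers"] = len(selection.markers)

    # ------------------------------------------------------------ cluster
    @_stage("cluster")
    def stage_cluster() -> tuple:
        profiles = build_profiles(normalized)
        mean_prof = profiles.mean_profiles()
        marker_mean = mean_prof.loc[
            mean_prof.index.intersection(selection.markers)
        ]
        emb = embed_tsne(
            marker_mean,
            TsneConfig(perplexity=cfg.perplexity, theta=cfg.theta, seed=cfg.seed),
        )
        model = fit_gmm_bic(
            emb, range(cfg.kmin, cfg.kmax + 1), seed=cfg.seed,
            n_init=cfg.gmm_restarts,
        )
        return profiles, mean_prof, emb, model

    profiles, mean_profiles, embedding, model = stage_cluster()
    counts["clusters"] = int(model.k)

    # ----------------------------------------------------------- annotate
    @_stage("annotate")
    def stage_annotate() -> tuple[ClusterAnnotation, dict, dict, list]:
        ann = annotate_clusters(
            model.labels, refs, fc_min=cfg.fc_min, q_max=cfg.q_max,
            min_votes=cfg.min_votes,
        )
        nb_map, overrides, dropped = _resolve_neighborhoods(
            ann, model.labels, refs
        )
        return ann, nb_map, overrides, dropped

    annotation, nb_map, nb_overrides, nb_dropped = stage_annotate()
    counts["neighborhood_map"] = {str(k): v for k, v in sorted(nb_map.items())}

    # ----------------------------------------------------------- classify
    @_stage("classify")
    def stage_classify() -> tuple:
        labels = model.labels[model.labels.isin(nb_map)]
        sizes = labels.value_counts()
        kept_clusters = sizes.index[sizes >= cfg.min_markers_per_cluster]
        dropped = sorted(set(sizes.index) - set(kept_clusters))
        if dropped:
            logger.warning("classify: clusters %s dropped (< %d markers)",
                           dropped, cfg.min_markers_per_cluster)
        labels = labels[labels.isin(kept_clusters)]
        svm_cfg = SvmConfig.preset(
            cfg.grid_preset, cv_folds=cfg.cv_folds,
            train_fraction=cfg.train_fraction, seed=cfg.seed, adapt_folds=True,
        )
        train_ids, test_ids = split_markers(labels, svm_cfg)
        per_rep = train_predict(profiles, labels.loc[train_ids], svm_cfg)
        merged = merge_replicates(per_rep)

        test_probs = merged.probabilities.loc[
            merged.probabilities.index.intersection(test_ids)
        ]
        cl_thresholds = calibrate_thresholds(
            test_probs, labels.loc[test_ids], "cluster",
            cfg.precision_floor_cluster,
        )
        eligible = merged.consistency >= 2
        cluster_calls = apply_thresholds(
            merged.probabilities, cl_thresholds, eligible=eligible
        )

        local_map = {c: nb_map[c] for c in merged.probabilities.columns}
        nb_probs = aggregate_neighborhood(merged.probabilities, local_map)
        nb_truth = labels.loc[test_ids].map(local_map)
        nb_thresholds = calibrate_thresholds(
            nb_probs.loc[nb_probs.index.intersection(test_ids)], nb_truth,
            "neighborhood", cfg.precision_floor_neighborhood,
        )
        nb_calls = apply_thresholds(nb_probs, nb_thresholds)
        assignments = reconcile_levels(
            cluster_calls, nb_calls, local_map,
            cluster_probs=merged.probabilities, neighborhood_probs=nb_probs,
        )
        return (labels, train_ids, test_ids, merged, cl_thresholds,
                nb_thresholds, nb_probs, assignments, local_map)

    (labels_used, train_ids, test_ids, merged, cl_thresholds, nb_thresholds,
     nb_probs, assignments, local_map) = stage_classify()
    n_all = len(assignments)
    n_cl = int((assignments["cluster"] != UNCLASSIFIED).sum())
    n_nb = int((assignments["neighborhood"] != UNCLASSIFIED).sum())
    counts["classified_cluster"] = {"n": n_cl, "pct": round(100 * n_cl / n_all, 1)}
    counts["classified_neighborhood"] = {
        "n": n_nb, "pct": round(100 * n_nb / n_all, 1)
    }
    counts["reconciled_unclassified"] = assignments.attrs["n_reconciled"]

    # ----------------------------------------------------------- evaluate
    @_stage("evaluate")
    def stage_evaluate() -> tuple[dict, dict, dict]:
        test_probs = merged.probabilities.loc[
            merged.probabilities.index.intersection(test_ids)
        ]
        m_cl = marker_metrics(
            test_probs, assignments["cluster"], labels_used.loc[test_ids]
        )
        m_nb = marker_metrics(
            nb_probs.loc[nb_probs.index.intersection(test_ids)],
            assignments["neighborhood"],
            labels_used.loc[test_ids].map(local_map),
        )
        reports = {}
        for name, ref in refs.items():
            mapped = map_reference_to_neighborhoods(ref)
            reports[name] = agreement(assignments, mapped)
        return m_cl, m_nb, reports

    metrics_cluster, metrics_neighborhood, agreement_reports = stage_evaluate()
    counts["marker_accuracy_cluster"] = {
        "pre": metrics_cluster["accuracy_pre"],
        "post": metrics_cluster["accuracy_post"],
    }
    counts["marker_accuracy_neighborhood"] = {
        "pre": metrics_neighborhood["accuracy_pre"],
        "post": metrics_neighborhood["accuracy_post"],
    }
    counts["agreement"] = {
        name: (None if r.agreement is None else round(r.agreement, 4))
        for name, r in agreement_reports.items()
    }

    # --------------------------------------------------- domains/complexes
    domain_table = complex_results = null_result = None
    if domains is not None:
        @_stage("domains")
        def stage_domains() -> pd.DataFrame:
            return domain_enrichment(
                domains, assignments, level="neighborhood",
                log2fc_cutoff=cfg.domain_log2fc_cutoff,
                q_cutoff=cfg.domain_q_cutoff,
                min_occurrence=cfg.domain_min_occurrence,
            )

        domain_table = stage_domains()
        counts["enriched_domains"] = int(domain_table["enriched"].sum())
    if complexes is not None:
        @_stage("complexes")
        def stage_complexes() -> tuple:
            res = complex_colocalization(
                complexes, mean_profiles, assignments,
                pcc_cutoff=cfg.complex_pcc_cutoff,
            )
            member_cc = complex_member_correlations(res)
            null = random_pair_null(
                mean_profiles, cfg.null_pairs, complexes, seed=cfg.seed,
                member_correlations=member_cc,
            )
            return res, null

        complex_results, null_result = stage_complexes()
        counts["full_coverage_complexes"] = sum(
            r.coverage == "full" for r in complex_results
        )
        counts["colocalized_complexes"] = sum(
            r.colocalized for r in complex_results
        )

    result = PipelineResult(
        config=cfg, experiment=experiment, normalized=normalized,
        marker_selection=selection, embedding=embedding, cluster_model=model,
        annotation=annotation, neighborhood_map=nb_map,
        neighborhood_overrides=nb_overrides, train_ids=train_ids,
        test_ids=test_ids, merged=merged, cluster_thresholds=cl_thresholds,
        neighborhood_thresholds=nb_thresholds, neighborhood_probs=nb_probs,
        assignments=assignments, metrics_cluster=metrics_cluster,
        metrics_neighborhood=metrics_neighborhood,
        agreement_reports=agreement_reports, domain_table=domain_table,
        complex_results=complex_results, null_result=null_result,
        manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write every stage output plus the manifest under ``outdir``."""
    import networkx as nx

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.normalized.to_frame().to_csv(out / "normalized.tsv", sep="\t",
                                        index=False)
    result.marker_selection.records.to_csv(out / "marker_records.tsv",
                                           sep="\t", index=False)
    result.embedding.coords.to_csv(out / "embedding.tsv", sep="\t")
    pd.DataFrame({
        "protein_id": result.cluster_model.labels.index,
        "cluster": result.cluster_model.labels.values,
    }).to_csv(out / "cluster_membership.tsv", sep="\t", index=False)
    result.annotation.votes.to_csv(out / "annotation_votes.tsv", sep="\t",
                                   index=False)
    pd.DataFrame(
        sorted(result.neighborhood_map.items()),
        columns=["cluster", "neighborhood"],
    ).to_csv(out / "neighborhood_map.tsv", sep="\t", index=False)
    pd.concat(
        [result.cluster_thresholds, result.neighborhood_thresholds]
    ).to_csv(out / "thresholds.tsv", sep="\t", index=False)
    result.merged.probabilities.to_csv(out / "probabilities_cluster.tsv",
                                       sep="\t")
    result.neighborhood_probs.to_csv(out / "probabilities_neighborhood.tsv",
                                     sep="\t")
    result.assignments.to_csv(out / "assignments.tsv", sep="\t")
    nodes, edges, g = export_network(result.assignments, result.neighborhood_map)
    nodes.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    nx.write_graphml(g, out / "network.graphml")
    if result.domain_table is not None:
        result.domain_table.to_csv(out / "domain_enrichment.tsv", sep="\t",
                                   index=False)
    if result.complex_results is not None:
        pd.DataFrame([
            {
                "complex_id": r.complex_id,
                "coverage": r.coverage,
                "n_members": len(r.members),
                "n_identified": len(r.identified),
                "n_retained": len(r.retained),
                "colocalized": r.colocalized,
            }
            for r in result.complex_results
        ]).to_csv(out / "complexes.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str)
    )
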