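"""Simulate organelle-fractionation quantification experiments with ground truth.

The generator emulates a six-organelle differential-enrichment design measured
in technical triplicate under two conditions (a parental line and a knockout).
Each protein belongs to one of ``n_clusters`` profile clusters; a cluster is
characterised by a fractionation profile concentrated on one or two dominant
organelle fractions.  On top of the clean cluster signal the generator plants
the nuisance structure the downstream analysis has to cope with:

* cross-organelle contamination — a fixed fraction of every protein's signal
  is redistributed uniformly over the six fractions (fractions are
  enrichments, not pure isolates);
* replicate noise — multiplicative lognormal error on every abundance entry;
  marker candidates are the low-noise population (``noise_sd``), all other
  proteins carry ``nonmarker_noise_multiplier`` times that noise;
* condition-unstable proteins — an independent profile per condition
  (replicate-stable within a condition, so only the cross-condition filter
  can catch them);
* multi-localized proteins — a blend of two cluster profiles from different
  neighborhoods whose mixing weight is re-drawn per replicate around 1/2
  (the partition ratio of a genuinely dual-localized protein fluctuates, so
  most fail the reproducibility filter; the consistent ones are the hard
  cases probability thresholds must reject);
* biological scatter — every protein carries a small individual perturbation
  of its cluster profile, fixed across replicates and conditions (no two real
  proteins share an identical fractionation profile; without this the
  embedding degenerates on duplicate points);
* missing values — low-intensity entries are preferentially censored, with
  the mean per-entry rate equal to ``missing_rate``.

Matching reference-annotation tables (three sources with configurable
coverage and error), a protein→domain table with planted neighborhood-specific
domains, and a complex-membership table with a configurable colocalized
fraction are produced alongside, all with full ground truth.

Reproducibility: every stochastic stage uses its own ``numpy`` generator
seeded as ``default_rng([seed, STAGE[name]])`` (see ``STAGE``), and stages run
in the fixed order of that table, so any stage can be re-executed in
isolation and identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ORGANELLES",
    "COMPARTMENTS",
    "NEIGHBORHOODS",
    "DEFAULT_NEIGHBORHOOD_OF_CLUSTER",
    "GeneratorConfig",
    "SimulatedExperiment",
    "simulate_experiment",
    "write_experiment",
]

ORGANELLES = ("PM", "ER", "Endosome", "Lysosome", "Golgi", "Mito")

NEIGHBORHOODS = ("secretory", "mitochondria", "nuclear", "cytosol", "ribosome")

#: 11-compartment annotation vocabulary used by the reference sources.
COMPARTMENTS = (
    "cytoskeleton",
    "cytosol",
    "nucleus",
    "endosome",
    "endoplasmic reticulum",
    "Golgi apparatus",
    "lysosome",
    "plasma membrane",
    "mitochondrion",
    "peroxisome",
    "ribosome",
)

#: Compartments a reference source may use for a cluster of each neighborhood.
_NEIGHBORHOOD_COMPARTMENTS = {
    "secretory": (
        "endoplasmic reticulum",
        "Golgi apparatus",
        "lysosome",
        "plasma membrane",
        "endosome",
        "peroxisome",
    ),
    "mitochondria": ("mitochondrion",),
    "nuclear": ("nucleus",),
    "cytosol": ("cytosol", "cytoskeleton"),
    "ribosome": ("ribosome",),
}


def _default_neighborhood_map(n_clusters: int = 18) -> dict[int, str]:
    """Clusters 1-3 secretory, 4-8 mitochondria, 9-11 nuclear, 12-17 cytosol,
    18 ribosome; other cluster counts scale the blocks proportionally."""
    if n_clusters == 18:
        blocks = [(3, "secretory"), (5, "mitochondria"), (3, "nuclear"),
                  (6, "cytosol"), (1, "ribosome")]
    else:
        if n_clusters < len(NEIGHBORHOODS):
            raise ValueError(
                f"n_clusters={n_clusters} is smaller than the number of "
                f"neighborhoods ({len(NEIGHBORHOODS)})"
            )
        base = [1] * len(NEIGHBORHOODS)
        extra = n_clusters - len(NEIGHBORHOODS)
        weights = np.array([3, 5, 3, 6, 1], dtype=float) / 18.0
        add = np.floor(weights * extra).astype(int)
        add[np.argsort(-(weights * extra - add))[: extra - add.sum()]] += 1
        blocks = [(b + a, nb) for (b, a), nb in zip(zip(base, add), NEIGHBORHOODS)]
    out: dict[int, str] = {}
    cid = 1
    for size, nb in blocks:
        for _ in range(size):
            out[cid] = nb
            cid += 1
    return out


DEFAULT_NEIGHBORHOOD_OF_CLUSTER = _default_neighborhood_map(18)

#: rng stream index per sampling stage (documented sampling order).
STAGE = {
    "cluster_plan": 0,
    "cluster_profiles": 1,
    "categories": 2,
    "cluster_assignment": 3,
    "unstable_profiles": 4,
    "abundance": 5,
    "multiloc_weights": 6,
    "noise": 7,
    "missing": 8,
    "references": 9,
    "domains": 10,
    "complexes": 11,
    "contamination": 12,
    "scatter": 13,
}


@dataclass
class GeneratorConfig:
    """Study-design parameters of a simulated fractionation experiment.

    Proportions are over all proteins and must satisfy
    ``marker_fraction + unstable_fraction + multiloc_fraction <= 1``;
    the remainder are stable but irreproducible ("other") proteins.
    """

    n_proteins: int = 2000
    n_clusters: int = 18
    neighborhood_map: dict[int, str] | None = None
    organelles: tuple[str, ...] = ORGANELLES
    n_replicates: int = 3
    conditions: tuple[str, str] = ("parental", "KO")
    marker_fraction: float = 0.35
    unstable_fraction: float = 0.10
    multiloc_fraction: float = 0.10
    contamination_rate: float = 0.05
    noise_sd: float = 0.1
    nonmarker_noise_multiplier: float = 3.0
    multiloc_weight_concentration: float = 5.0
    scatter_concentration: float | None = 200.0
    missing_rate: float = 0.05
    annotation_coverage: dict[str, float] = field(
        default_factory=lambda: {"uniprot": 0.7, "go": 0.7, "mouse": 0.5}
    )
    annotation_error: dict[str, float] = field(
        default_factory=lambda: {"uniprot": 0.05, "go": 0.05, "mouse": 0.05}
    )
    n_background_domains: int = 40
    n_planted_domains: int = 3
    planted_domain_rate: float = 0.40
    background_domain_rate: float = 0.01
    n_complexes: int = 40
    colocalized_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or int(self.n_proteins) != self.n_proteins:
            raise ValueError("n_proteins must be a positive integer")
        if self.n_clusters <= 0 or int(self.n_clusters) != self.n_clusters:
            raise ValueError("n_clusters must be a positive integer")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(set(self.organelles)) != 6:
            raise ValueError("organelles must be 6 distinct labels")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")
        for name in (
            "marker_fraction", "unstable_fraction", "multiloc_fraction",
            "contamination_rate", "missing_rate", "colocalized_fraction",
            "planted_domain_rate", "background_domain_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.marker_fraction + self.unstable_fraction + self.multiloc_fraction > 1:
            raise ValueError(
                "marker_fraction + unstable_fraction + multiloc_fraction > 1"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nonmarker_noise_multiplier < 1:
            raise ValueError("nonmarker_noise_multiplier must be >= 1")
        if self.scatter_concentration is not None and self.scatter_concentration <= 0:
            raise ValueError("scatter_concentration must be positive or None")
        for d in (self.annotation_coverage, self.annotation_error):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"annotation rate {k}={v} outside [0, 1]")
        if self.neighborhood_map is None:
            self.neighborhood_map = _default_neighborhood_map(self.n_clusters)
        else:
            missing = set(range(1, self.n_clusters + 1)) - set(self.neighborhood_map)
            if missing:
                raise ValueError(f"neighborhood_map misses clusters {sorted(missing)}")
            if self.n_clusters < len(set(self.neighborhood_map.values())):
                raise ValueError("n_clusters < number of neighborhoods")


@dataclass
class SimulatedExperiment:
    """Bundle of generator outputs; the ``truth`` table is the ground truth.

    ``truth`` columns: protein_id, true_cluster, second_cluster (multi-localized
    only, else <NA>), true_neighborhood, true_compartment,
    is_stable_marker_candidate, is_unstable, is_multiloc.
    """

    quant: pd.DataFrame                 # protein_id + 12 sample columns
    truth: pd.DataFrame
    references: dict[str, pd.DataFrame]  # source -> (protein_id, compartment)
    domains: pd.DataFrame               # protein_id, domains, signal/transit/tm
    complexes: pd.DataFrame             # complex_id, member protein_ids
    cluster_profiles: pd.DataFrame      # cluster x organelle expected profile
    cluster_compartment: dict[int, str]
    planted_domains: pd.DataFrame       # domain, neighborhood
    config: GeneratorConfig


def _rng(cfg: GeneratorConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, STAGE[stage]])


def _dominant_sets(n_clusters: int, rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Distinct 1- or 2-organelle dominant sets, seeded order, singletons first.

    Distinctness keeps the cluster centroids separable; pairs sharing an
    organelle still sit adjacent, so neighborhood merging stays non-trivial.
    """
    singles = [(i,) for i in range(6)]
    pairs = list(itertools.combinations(range(6), 2))
    pool = [singles[i] for i in rng.permutation(len(singles))]
    pool += [pairs[i] for i in rng.permutation(len(pairs))]
    return [pool[i % len(pool)] for i in range(n_clusters)]


def _cluster_profiles(cfg: GeneratorConfig) -> np.ndarray:
    """Characteristic profile per cluster: Dirichlet over the dominant set.

    Support is exactly the dominant organelles; off-dominant signal in the
    data comes only from contamination (and jitter for non-marker proteins).
    """
    rng = _rng(cfg, "cluster_plan")
    sets = _dominant_sets(cfg.n_clusters, rng)
    rng_p = _rng(cfg, "cluster_profiles")
    profiles = np.zeros((cfg.n_clusters, 6))
    for k, dom in enumerate(sets):
        if len(dom) == 1:
            profiles[k, dom[0]] = 1.0
        else:
            w = rng_p.dirichlet([60 * 0.55, 60 * 0.45])
            profiles[k, list(dom)] = w
    return profiles


def _assign_categories(cfg: GeneratorConfig) -> np.ndarray:
    """Per-protein category: 0 marker, 1 unstable, 2 multiloc, 3 other."""
    rng = _rng(cfg, "categories")
    p = [
        cfg.marker_fraction,
        cfg.unstable_fraction,
        cfg.multiloc_fraction,
        1.0 - cfg.marker_fraction - cfg.unstable_fraction - cfg.multiloc_fraction,
    ]
    return rng.choice(4, size=cfg.n_proteins, p=p)


def _contaminate(profile: np.ndarray, rate: float,
                 background: np.ndarray) -> np.ndarray:
    """Blend ``rate`` of the signal into the protein's background profile.

    The background is uniform in expectation but protein-specific and fixed
    across conditions and replicates: a protein's off-target co-sedimentation
    is reproducible.  (Exactly uniform contamination would make the
    off-dominant entries exact ties whose ranks are pure noise, and rank
    correlations of genuinely stable proteins would be meaningless.)
    """
    return (1.0 - rate) * profile + rate * background


def _jitter(profile: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet re-draw around ``profile`` restricted to its support."""
    support = profile > 0
    out = np.zeros_like(profile)
    out[support] = rng.dirichlet(profile[support] * kappa)
    return out


def simulate_experiment(config: GeneratorConfig) -> SimulatedExperiment:
    """Run the full generator; identical configs give byte-identical tables."""
    cfg = config
    n = cfg.n_proteins
    protein_ids = [f"P{i + 1:05d}" for i in range(n)]
    profiles = _cluster_profiles(cfg)
    nb_map = cfg.neighborhood_map
    assert nb_map is not None

    category = _assign_categories(cfg)
    is_marker = category == 0
    is_unstable = category == 1
    is_multiloc = category == 2

    rng_assign = _rng(cfg, "cluster_assignment")
    true_cluster = rng_assign.integers(1, cfg.n_clusters + 1, size=n)
    second_cluster = np.full(n, -1)
    for i in np.flatnonzero(is_multiloc):
        nb = nb_map[int(true_cluster[i])]
        others = [c for c in range(1, cfg.n_clusters + 1) if nb_map[c] != nb]
        second_cluster[i] = others[rng_assign.integers(len(others))]

    # condition-unstable proteins: independent dominant-set profile in KO
    rng_un = _rng(cfg, "unstable_profiles")
    unstable_ko = np.zeros((n, 6))
    for i in np.flatnonzero(is_unstable):
        k = rng_un.integers(1, 3)
        dom = rng_un.choice(6, size=k, replace=False)
        prof = np.zeros(6)
        if k == 1:
            prof[dom[0]] = 1.0
        else:
            prof[dom] = rng_un.dirichlet([60 * 0.55, 60 * 0.45])
        unstable_ko[i] = prof

    rng_ab = _rng(cfg, "abundance")
    abundance = rng_ab.lognormal(mean=11.0, sigma=1.0, size=n)

    # per-(protein, condition) component profiles: primary (own cluster,
    # both conditions unless unstable) and secondary (multi-localized only)
    primary = np.zeros((n, 2, 6))
    secondary = np.zeros((n, 6))
    for i in range(n):
        primary[i, 0] = profiles[true_cluster[i] - 1]
        primary[i, 1] = unstable_ko[i] if is_unstable[i] else primary[i, 0]
        if is_multiloc[i]:
            secondary[i] = profiles[second_cluster[i] - 1]

    # per-protein reproducible contamination background (uniform on average)
    rng_bg = _rng(cfg, "contamination")
    backgrounds = rng_bg.dirichlet(np.full(6, 15.0), size=n)
    for i in range(n):
        for c in range(2):
            primary[i, c] = _contaminate(
                primary[i, c], cfg.contamination_rate, backgrounds[i]
            )
        if is_multiloc[i]:
            secondary[i] = _contaminate(
                secondary[i], cfg.contamination_rate, backgrounds[i]
            )

    # biological scatter: protein-individual profile, shared by both
    # conditions for condition-stable proteins, per condition for unstable
    rng_s = _rng(cfg, "scatter")
    if cfg.scatter_concentration is not None:
        for i in range(n):
            primary[i, 0] = _jitter(primary[i, 0], cfg.scatter_concentration,
                                    rng_s)
            if is_unstable[i]:
                primary[i, 1] = _jitter(primary[i, 1],
                                        cfg.scatter_concentration, rng_s)
            else:
                primary[i, 1] = primary[i, 0]
            if is_multiloc[i]:
                secondary[i] = _jitter(secondary[i], cfg.scatter_concentration,
                                       rng_s)

    # per-(protein, condition, replicate) realized profile; multi-localized
    # proteins re-draw their mixing weight (mean 1/2) every replicate
    rng_w = _rng(cfg, "multiloc_weights")
    realized = np.zeros((n, 2, cfg.n_replicates, 6))
    for i in range(n):
        for c in range(2):
            for r in range(cfg.n_replicates):
                if is_multiloc[i]:
                    w = rng_w.beta(cfg.multiloc_weight_concentration,
                                   cfg.multiloc_weight_concentration)
                    realized[i, c, r] = (
                        w * primary[i, c] + (1.0 - w) * secondary[i]
                    )
                else:
                    realized[i, c, r] = primary[i, c]

    # abundances with multiplicative lognormal noise; noise drawn as
    # sd * standard normal so raising noise_sd rescales the same draws;
    # marker candidates (and unstable proteins, within a condition) are the
    # low-noise population
    rng_n = _rng(cfg, "noise")
    z = rng_n.standard_normal(size=(n, 2, cfg.n_replicates, 6))
    sd = np.where(
        is_marker | is_unstable, cfg.noise_sd,
        cfg.noise_sd * cfg.nonmarker_noise_multiplier,
    )[:, None, None, None]
    values = abundance[:, None, None, None] * realized * np.exp(sd * z)

    # missingness is intensity-dependent (left-censoring, as in MS data):
    # per entry, p_missing ∝ (1 - relative intensity)^4, renormalized within
    # each 6-fraction profile so the mean per-entry rate equals missing_rate
    rng_m = _rng(cfg, "missing")
    w = (1.0 - realized) ** 4
    w_mean = w.mean(axis=3, keepdims=True)
    p_missing = np.clip(
        cfg.missing_rate * np.divide(w, np.where(w_mean > 0, w_mean, 1.0)),
        0.0, 1.0,
    )
    missing = rng_m.random(size=values.shape) < p_missing

    columns, data = ["protein_id"], {"protein_id": protein_ids}
    for o_idx, org in enumerate(cfg.organelles):
        for c_idx, cond in enumerate(cfg.conditions):
            for r in range(cfg.n_replicates):
                col = f"{org}_{cond}_R{r + 1}"
                columns.append(col)
                v = values[:, c_idx, r, o_idx].copy()
                v[missing[:, c_idx, r, o_idx]] = np.nan
                data[col] = v
    quant = pd.DataFrame(data, columns=columns)

    cluster_compartment: dict[int, str] = {}
    counters: dict[str, int] = {}
    for c in range(1, cfg.n_clusters + 1):
        nb = nb_map[c]
        vocab = _NEIGHBORHOOD_COMPARTMENTS[nb]
        idx = counters.get(nb, 0)
        cluster_compartment[c] = vocab[idx % len(vocab)]
        counters[nb] = idx + 1

    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "true_cluster": true_cluster,
            "second_cluster": pd.array(
                [c if c > 0 else None for c in second_cluster], dtype="Int64"
            ),
            "true_neighborhood": [nb_map[int(c)] for c in true_cluster],
            "true_compartment": [cluster_compartment[int(c)] for c in true_cluster],
            "is_stable_marker_candidate": is_marker,
            "is_unstable": is_unstable,
            "is_multiloc": is_multiloc,
        }
    )

    rng_ref = _rng(cfg, "references")
    references: dict[str, pd.DataFrame] = {}
    for source in ("uniprot", "go", "mouse"):
        cov = cfg.annotation_coverage.get(source, 0.0)
        err = cfg.annotation_error.get(source, 0.0)
        covered = rng_ref.random(n) < cov
        wrong = rng_ref.random(n) < err
        rows = []
        for i in np.flatnonzero(covered):
            comp = cluster_compartment[int(true_cluster[i])]
            if wrong[i]:
                alternatives = [c for c in COMPARTMENTS if c != comp]
                comp = alternatives[rng_ref.integers(len(alternatives))]
            rows.append((protein_ids[i], comp))
        references[source] = pd.DataFrame(rows, columns=["protein_id", "compartment"])

    rng_d = _rng(cfg, "domains")
    bg_names = [f"PF{i + 1:05d}" for i in range(cfg.n_background_domains)]
    planted_names = [f"PFX{i + 1:04d}" for i in range(cfg.n_planted_domains)]
    # planted localization-specific domains live in compact neighborhoods:
    # a domain spread over a neighborhood holding a fraction f of the
    # proteome can reach at most fold change 1/f, so classes covering a
    # third of the proteome can never clear a 4-fold enrichment cutoff
    nb_sizes = pd.Series(list(nb_map.values())).value_counts()
    compact = [
        nb for nb in NEIGHBORHOODS
        if nb in nb_sizes and nb_sizes[nb] / cfg.n_clusters <= 0.2
    ] or list(NEIGHBORHOODS)
    planted_nbs = [
        compact[rng_d.integers(len(compact))]
        for _ in range(cfg.n_planted_domains)
    ]
    dom_rows = []
    nb_of_protein = truth["true_neighborhood"].to_numpy()
    for i in range(n):
        doms = list(rng_d.choice(bg_names, size=rng_d.poisson(0.8), replace=False)
                    if cfg.n_background_domains else [])
        for name, nb in zip(planted_names, planted_nbs):
            rate = (
                cfg.planted_domain_rate
                if nb_of_protein[i] == nb
                else cfg.background_domain_rate
            )
            if rng_d.random() < rate:
                doms.append(name)
        nb = nb_of_protein[i]
        signal = rng_d.random() < (0.6 if nb == "secretory" else 0.03)
        transit = rng_d.random() < (0.6 if nb == "mitochondria" else 0.02)
        tm = rng_d.random() < (0.4 if nb == "secretory" else 0.1)
        dom_rows.append((protein_ids[i], ";".join(doms), signal, transit, tm))
    domains = pd.DataFrame(
        dom_rows,
        columns=["protein_id", "domains", "signal_peptide", "transit_peptide",
                 "transmembrane"],
    )
    planted_domains = pd.DataFrame(
        {"domain": planted_names, "neighborhood": planted_nbs}
    )

    # complexes drawn from marker-candidate proteins (tight profiles);
    # colocalized complexes from one cluster, the rest across clusters
    rng_c = _rng(cfg, "complexes")
    members_by_cluster = {
        c: [protein_ids[i] for i in np.flatnonzero(is_marker & (true_cluster == c))]
        for c in range(1, cfg.n_clusters + 1)
    }
    cx_rows = []
    for j in range(cfg.n_complexes):
        size = min(6, 2 + rng_c.poisson(2.0))
        coloc = rng_c.random() < cfg.colocalized_fraction
        if coloc:
            eligible = [c for c, m in members_by_cluster.items() if len(m) >= size]
            if not eligible:
                continue
            c = eligible[rng_c.integers(len(eligible))]
            members = list(rng_c.choice(members_by_cluster[c], size=size,
                                        replace=False))
        else:
            clusters = rng_c.choice(
                [c for c, m in members_by_cluster.items() if m],
                size=size, replace=False,
            )
            members = [
                members_by_cluster[c][rng_c.integers(len(members_by_cluster[c]))]
                for c in clusters
            ]
        cx_rows.append((f"CPX{j + 1:04d}", ";".join(members), coloc))
    complexes = pd.DataFrame(
        cx_rows, columns=["complex_id", "members", "planted_colocalized"]
    )

    cluster_profiles = pd.DataFrame(
        profiles, index=pd.RangeIndex(1, cfg.n_clusters + 1, name="cluster"),
        columns=list(cfg.organelles),
    )
    return SimulatedExperiment(
        quant=quant,
        truth=truth,
        references=references,
        domains=domains,
        complexes=complexes,
        cluster_profiles=cluster_profiles,
        cluster_compartment=cluster_compartment,
        planted_domains=planted_domains,
        config=cfg,
    )


def write_experiment(exp: SimulatedExperiment, outdir) -> None:
    """Write all generator tables plus a manifest to ``outdir`` (TSV/JSON)."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    exp.quant.to_csv(out / "quant.tsv", sep="\t", index=False)
    exp.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    for source, ref in exp.references.items():
        ref.to_csv(out / f"reference_{source}.tsv", sep="\t", index=False)
    exp.domains.to_csv(out / "domains.tsv", sep="\t", index=False)
    exp.complexes.to_csv(out / "complexes.tsv", sep="\t", index=False)
    exp.cluster_profiles.to_csv(out / "cluster_profiles.tsv", sep="\t")
    cfg = asdict(exp.config)
    cfg["organelles"] = list(cfg["organelles"])
    cfg["conditions"] = list(cfg["conditions"])
    cfg["neighborhood_map"] = {str(k): v for k, v in cfg["neighborhood_map"].items()}
    (out / "manifest.json").write_text(json.dumps({"config": cfg}, indent=2))
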