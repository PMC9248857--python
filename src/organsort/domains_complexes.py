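"""Domain-localization enrichment and protein-complex colocalization.

Domain enrichment asks which domain accessions are over-represented among
the proteins assigned to a cluster or neighborhood, using the same fold
change and hypergeometric machinery as cluster annotation, with a log2
fold-change cutoff (default 2, i.e. 4-fold), a q-value cutoff and a minimum
occurrence count.  Complex colocalization asks whether the members of a
curated complex share a fractionation profile and a neighborhood: members
whose mean Pearson correlation to their co-members falls below a cutoff are
prefiltered, complexes with every member identified and surviving are
"full coverage", and a complex is colocalized when all retained members share
one neighborhood call.  A random-pair null (pairs that are not co-members of
any complex) gives the comparison distribution for member correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import UNCLASSIFIED
from .cluster_annotate import bh_adjust, enrichment_test

logger = logging.getLogger(__name__)


def parse_members(cell: str) -> list[str]:
    return [m for m in str(cell).split(";") if m]


def domain_enrichment(
    domains: pd.DataFrame,
    assignments: pd.DataFrame,
    level: str = "neighborhood",
    log2fc_cutoff: float = 2.0,
    q_cutoff: float = 0.05,
    min_occurrence: int = 3,
    cutoff_scale: str = "log2fc",
) -> pd.DataFrame:
    """Per-(domain, class) enrichment among proteins assigned at ``level``.

    ``cutoff_scale="log2fc"`` keeps log2(FC) >= cutoff (default); ``"fc"``
    applies the cutoff to the raw fold change instead.  BH correction is
    applied across all (domain, class) tests; hits also need q < ``q_cutoff``
    and at least ``min_occurrence`` carriers in the class.
    """
    if len(domains) == 0:
        raise ValueError("empty domain table")
    if cutoff_scale not in ("log2fc", "fc"):
        raise ValueError(f"unknown cutoff_scale {cutoff_scale!r}")
    calls = assignments[level]
    assigned = calls[calls != UNCLASSIFIED]
    dom_lists = domains.set_index("protein_id")["domains"].map(parse_members)
    dom_lists = dom_lists.reindex(assigned.index).dropna()
    carriers: dict[str, set[str]] = {}
    for pid, doms in dom_lists.items():
        for d in set(doms):
            carriers.setdefault(d, set()).add(pid)
    N = len(assigned)
    rows = []
    for cls in sorted(assigned.unique(), key=str):
        members = set(assigned.index[assigned == cls])
        n = len(members)
        for d, carrier_set in sorted(carriers.items()):
            B = len(carrier_set)
            b = len(carrier_set & members)
            r = enrichment_test(b, n, B, N)
            rows.append((d, cls, r.b, r.n, r.B, r.N, r.fc, r.p))
    table = pd.DataFrame(
        rows, columns=["domain", "class", "b", "n", "B", "N", "fc", "p"]
    )
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    with np.errstate(divide="ignore"):
        table["log2fc"] = np.log2(table["fc"].where(table["fc"] > 0, np.nan))
    stat = table["log2fc"] if cutoff_scale == "log2fc" else table["fc"]
    cut = log2fc_cutoff
    table["enriched"] = (
        (stat >= cut) & (table["q"] < q_cutoff) & (table["b"] >= min_occurrence)
    )
    logger.info("domain_enrichment: %d enriched (domain, %s) pairs",
                int(table["enriched"].sum()), level)
    return table


@dataclass
class ComplexResult:
    complex_id: str
    coverage: str                     # full | partial | none
    members: list[str]
    identified: list[str]
    retained: list[str]
    pcc: pd.DataFrame | None          # pairwise PCC among identified members
    neighborhoods: dict[str, str]
    colocalized: bool


def complex_colocalization(
    complexes: pd.DataFrame,
    mean_profiles: pd.DataFrame,
    assignments: pd.DataFrame,
    pcc_cutoff: float = 0.8,
) -> list[ComplexResult]:
    """Coverage, member-correlation prefilter and colocalization per complex.

    A member is prefiltered when its mean pairwise Pearson correlation to the
    other identified members is below ``pcc_cutoff``.  Coverage is "full"
    when every member is identified and survives, "none" when fewer than two
    members are identified, else "partial".  A complex is colocalized when
    its >= 2 retained members all carry the same (non-unclassified)
    neighborhood call.
    """
    results = []
    for _, row in complexes.iterrows():
        members = parse_members(row["members"])
        identified = [m for m in members if m in mean_profiles.index]
        nbs = {
            m: assignments.loc[m, "neighborhood"]
            for m in identified if m in assignments.index
        }
        if len(identified) < 2:
            results.append(ComplexResult(
                complex_id=row["complex_id"], coverage="none", members=members,
                identified=identified, retained=[], pcc=None,
                neighborhoods=nbs, colocalized=False,
            ))
            continue
        block = mean_profiles.loc[identified].to_numpy()
        cc = np.corrcoef(block)
        cc = np.atleast_2d(cc)
        pcc = pd.DataFrame(cc, index=identified, columns=identified)
        mean_to_others = (cc.sum(axis=1) - np.diag(cc)) / (len(identified) - 1)
        retained = [m for m, v in zip(identified, mean_to_others)
                    if v >= pcc_cutoff]
        full = len(identified) == len(members) and len(retained) == len(members)
        coverage = "full" if full else "partial"
        ret_nbs = {nbs.get(m, UNCLASSIFIED) for m in retained}
        colocalized = (
            len(retained) >= 2
            and len(ret_nbs) == 1
            and UNCLASSIFIED not in ret_nbs
        )
        results.append(ComplexResult(
            complex_id=row["complex_id"], coverage=coverage, members=members,
            identified=identified, retained=retained, pcc=pcc,
            neighborhoods=nbs, colocalized=colocalized,
        ))
    n_full = sum(r.coverage == "full" for r in results)
    logger.info("complex_colocalization: %d/%d full-coverage complexes",
                n_full, len(results))
    return results


def complex_member_correlations(results: list[ComplexResult]) -> np.ndarray:
    """All pairwise member correlations over identified members of all
    complexes (upper triangles, concatenated)."""
    out = []
    for r in results:
        if r.pcc is None:
            continue
        arr = r.pcc.to_numpy()
        iu = np.triu_indices_from(arr, k=1)
        out.extend(arr[iu].tolist())
    return np.asarray(out)


def random_pair_null(
    mean_profiles: pd.DataFrame,
    n_pairs: int,
    exclusion: pd.DataFrame,
    seed: int,
    member_correlations: np.ndarray | None = None,
) -> dict:
    """Null distribution of profile correlations over non-co-member pairs.

    Samples ``n_pairs`` distinct protein pairs that are not co-members of any
    complex in ``exclusion`` and computes their Pearson correlations; when
    ``member_correlations`` is given, also reports the two-sample
    Kolmogorov-Smirnov statistic between member and null correlations.
    """
    ids = list(mean_profiles.index)
    n = len(ids)
    excluded = set()
    for _, row in exclusion.iterrows():
        members = [m for m in parse_members(row["members"]) if m in mean_profiles.index]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                excluded.add(frozenset((a, b)))
    total = n * (n - 1) // 2 - len(excluded)
    if n_pairs > total:
        raise ValueError(f"n_pairs={n_pairs} exceeds {total} available pairs")
    rng = np.random.default_rng(seed)
    chosen: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    while len(chosen) < n_pairs:
        i, j = rng.integers(n), rng.integers(n)
        if i == j:
            continue
        key = frozenset((ids[i], ids[j]))
        if key in excluded or key in seen:
            continue
        seen.add(key)
        chosen.append((ids[i], ids[j]))
    arr = mean_profiles.to_numpy()
    pos = {pid: k for k, pid in enumerate(ids)}
    pcc = np.array([
        np.corrcoef(arr[pos[a]], arr[pos[b]])[0, 1] for a, b in chosen
    ])
    out = {"pairs": chosen, "pcc": pcc}
    if member_correlations is not None and len(member_correlations):
        ks = stats.ks_2samp(member_correlations, pcc)
        out["ks_statistic"] = float(ks.statistic)
        out["ks_pvalue"] = float(ks.pvalue)
    return out
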