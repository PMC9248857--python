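"""Quantification-table I/O, median normalization and profile construction.

A quantification table is a protein × sample matrix whose sample columns are
keyed ``<organelle>_<condition>_R<replicate>``.  Profiles are per-replicate
relative-abundance vectors over (organelle × condition); they are what the
embedding and the classifiers consume.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SAMPLE_RE = re.compile(r"^(?P<organelle>.+)_(?P<condition>[^_]+)_R(?P<replicate>\d+)$")


@dataclass
class QuantTable:
    """Protein × sample abundances; missing values are NaN, zeros are zeros.

    ``data`` is indexed by protein_id with columns a MultiIndex
    (organelle, condition, replicate).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.data.columns
        if not isinstance(cols, pd.MultiIndex) or cols.names != [
            "organelle", "condition", "replicate",
        ]:
            raise ValueError("columns must be a (organelle, condition, replicate) MultiIndex")
        if cols.duplicated().any():
            raise ValueError("duplicate sample keys")
        with np.errstate(invalid="ignore"):
            if (self.data.to_numpy() < 0).any():
                raise ValueError("negative abundances")

    @property
    def organelles(self) -> list[str]:
        return list(self.data.columns.get_level_values("organelle").unique())

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns.get_level_values("condition").unique())

    @property
    def replicates(self) -> list[int]:
        return sorted(self.data.columns.get_level_values("replicate").unique())

    def to_frame(self) -> pd.DataFrame:
        """Flat frame with ``protein_id`` column and ``org_cond_Rk`` headers."""
        flat = self.data.copy()
        flat.columns = [f"{o}_{c}_R{r}" for o, c, r in flat.columns]
        return flat.reset_index()


@dataclass
class ProfileMatrix:
    """Per-(protein, replicate) relative profiles over (organelle, condition).

    Rows sum to 1 except rows that were fully missing in a replicate, which
    are flagged and excluded from classification for that replicate.
    """

    values: pd.DataFrame          # index (protein_id, replicate)
    flagged: pd.Series            # bool per (protein_id, replicate)
    scheme: str = "per-replicate-concat-conditions"
    condition: str | None = None  # set for the per-condition scheme

    def mean_profiles(self, valid_only: bool = True) -> pd.DataFrame:
        """Replicate-averaged profile per protein (rows renormalized to 1)."""
        vals = self.values[~self.flagged] if valid_only else self.values
        mean = vals.groupby(level="protein_id", sort=False).mean()
        s = mean.sum(axis=1)
        return mean.div(s.where(s > 0, 1.0), axis=0)


def _parse_sample_key(col: str) -> tuple[str, str, int]:
    m = _SAMPLE_RE.match(col)
    if m is None:
        raise ValueError(f"unparseable sample key: {col!r}")
    return m["organelle"], m["condition"], int(m["replicate"])


def quant_table_from_frame(frame: pd.DataFrame) -> QuantTable:
    """Build a QuantTable from a flat frame (``protein_id`` + sample columns)."""
    if "protein_id" not in frame.columns:
        raise ValueError("missing protein_id column")
    dup = frame["protein_id"][frame["protein_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate protein ids: {sorted(set(dup))}")
    sample_cols = [c for c in frame.columns if c != "protein_id"]
    keys = [_parse_sample_key(c) for c in sample_cols]
    data = frame.set_index("protein_id")[sample_cols].astype(float)
    data.columns = pd.MultiIndex.from_tuples(
        keys, names=["organelle", "condition", "replicate"]
    )
    return QuantTable(data)


def read_quant_table(path, dialect: str = "default") -> QuantTable:
    """Read a TSV quantification table.

    The single supported dialect names samples ``<organelle>_<condition>_R<k>``.
    Empty cells are missing; zeros are genuine zeros.
    """
    if dialect != "default":
        raise ValueError(f"unknown dialect {dialect!r}")
    frame = pd.read_csv(path, sep="\t")
    n_before = len(frame)
    frame = frame.dropna(how="all", subset=[c for c in frame.columns if c != "protein_id"])
    if len(frame) != n_before:
        logger.info("read_quant_table: dropped %d all-missing rows", n_before - len(frame))
    q = quant_table_from_frame(frame)
    logger.info(
        "read_quant_table: %d proteins x %d samples", q.data.shape[0], q.data.shape[1]
    )
    return q


def median_normalize(q: QuantTable) -> QuantTable:
    """Divide each sample column by its median over present values.

    Missing entries are preserved.  The direction (each sample's median
    becomes 1) is a recorded convention; the procedure is idempotent.
    """
    med = q.data.median(axis=0, skipna=True)
    if med.isna().any():
        bad = [c for c in q.data.columns[med.isna()]]
        raise ValueError(f"columns entirely missing: {bad}")
    if (med == 0).any():
        bad = [c for c in q.data.columns[med == 0]]
        raise ValueError(f"columns with zero median: {bad}")
    return QuantTable(q.data / med)


def build_profiles(
    q: QuantTable, scheme: str = "per-replicate-concat-conditions"
) -> ProfileMatrix | dict[str, ProfileMatrix]:
    """Build per-replicate relative profiles.

    Default scheme concatenates both conditions into one 12-feature vector per
    replicate (markers are required to be condition-stable, so the two
    condition blocks are near-duplicates that damp noise).  The alternative
    ``per-replicate-per-condition`` returns one 6-feature ProfileMatrix per
    condition.  Missing entries are imputed as zero before renormalization —
    absence from an organelle fraction is informative in enrichment designs —
    and rows with no signal at all in a replicate are flagged.
    """
    if scheme == "per-replicate-per-condition":
        return {
            cond: _profiles_for(q, [cond]) for cond in q.conditions
        }
    if scheme != "per-replicate-concat-conditions":
        raise ValueError(f"unknown scheme {scheme!r}")
    return _profiles_for(q, q.conditions)


def _profiles_for(q: QuantTable, conditions: list[str]) -> ProfileMatrix:
    organelles = q.organelles
    replicates = q.replicates
    feat_cols = pd.MultiIndex.from_tuples(
        [(o, c) for o in organelles for c in conditions],
        names=["organelle", "condition"],
    )
    rows, flags, index = [], [], []
    for rep in replicates:
        sub = q.data.loc[:, [(o, c, rep) for o, c in feat_cols]]
        arr = np.nan_to_num(sub.to_numpy(), nan=0.0)
        total = arr.sum(axis=1)
        flagged = total <= 0
        norm = arr / np.where(flagged, 1.0, total)[:, None]
        for i, pid in enumerate(q.data.index):
            index.append((pid, rep))
            rows.append(norm[i])
            flags.append(bool(flagged[i]))
    idx = pd.MultiIndex.from_tuples(index, names=["protein_id", "replicate"])
    values = pd.DataFrame(rows, index=idx, columns=feat_cols)
    flagged_s = pd.Series(flags, index=idx, name="flagged")
    if flagged_s.any():
        logger.info("build_profiles: %d (protein, replicate) rows fully missing",
                    int(flagged_s.sum()))
    return ProfileMatrix(
        values=values,
        flagged=flagged_s,
        scheme="per-replicate-concat-conditions" if len(conditions) > 1
        else "per-replicate-per-condition",
        condition=conditions[0] if len(conditions) == 1 else None,
    )
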