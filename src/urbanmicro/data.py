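"""Core containers for OTU abundance data and sample/city annotations.

An :class:`AbundanceTable` is an OTU-by-sample matrix of nonnegative integer
counts with a full taxonomic lineage per OTU.  Rows can be restricted to a
kingdom category and aggregated (summed) to a coarser taxonomic rank with
:func:`split_by_stratum`, mirroring the read/assembly x kingdom x rank
stratification used when screening urban metagenome profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered taxonomic ranks stored for every OTU.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Aggregation levels accepted by :class:`StratumKey` ("otu" = no aggregation).
LEVELS = ("phylum", "class", "order", "family", "genus", "otu")

#: Sentinel used for a missing rank in a lineage.
UNCLASSIFIED = "unclassified"

#: Kingdom categories; each maps to the set of kingdom labels it covers.
CATEGORY_KINGDOMS: dict[str, frozenset[str]] = {
    "Bacteria-Archaea": frozenset({"Bacteria", "Archaea"}),
    "Eukarya": frozenset({"Eukarya", "Eukaryota"}),
    "Virus": frozenset({"Virus", "Viruses"}),
}


class ValidationError(ValueError):
    """Raised when a table or metadata file violates a structural invariant."""


def _pad_lineage(lineage: Sequence[str]) -> tuple[str, ...]:
    """Pad/truncate a lineage to the seven canonical ranks."""
    padded = list(lineage[: len(RANKS)])
    padded += [UNCLASSIFIED] * (len(RANKS) - len(padded))
    return tuple(x if x else UNCLASSIFIED for x in padded)


@dataclass
class AbundanceTable:
    """OTU x sample integer count matrix with per-OTU taxonomy.

    Parameters
    ----------
    otu_ids
        Unique, stable row identifiers.
    lineages
        Mapping ``otu_id -> (kingdom, phylum, class, order, family, genus,
        species)``; missing ranks carry the ``"unclassified"`` sentinel.
    counts
        ``(n_otus, n_samples)`` array of nonnegative integers.
    sample_ids
        Unique column identifiers.
    """

    otu_ids: list[str]
    lineages: dict[str, tuple[str, ...]]
    counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.otu_ids = list(self.otu_ids)
        self.sample_ids = list(self.sample_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValidationError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValidationError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at OTU {self.otu_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        missing = [o for o in self.otu_ids if o not in self.lineages]
        if missing:
            raise ValidationError(f"missing lineage for OTUs: {missing[:5]}")
        self.lineages = {o: _pad_lineage(self.lineages[o]) for o in self.otu_ids}

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def subset_otus(self, keep: Sequence[str]) -> "AbundanceTable":
        """Restrict rows to ``keep`` (order preserved as given)."""
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        rows = [idx[o] for o in keep]
        return AbundanceTable(
            otu_ids=list(keep),
            lineages={o: self.lineages[o] for o in keep},
            counts=self.counts[rows],
            sample_ids=self.sample_ids,
        )

    def subset_samples(self, keep: Sequence[str]) -> "AbundanceTable":
        """Restrict columns to ``keep`` (order preserved as given)."""
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in keep]
        return AbundanceTable(
            otu_ids=list(self.otu_ids),
            lineages=dict(self.lineages),
            counts=self.counts[:, cols],
            sample_ids=list(keep),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and self.lineages == other.lineages
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: city, collection year and sequencing depth.

    ``total_reads`` is the library size N_i used as the model offset; it is
    the sequencing depth and may exceed the classified column sum.
    """

    frame: pd.DataFrame  # index: sample_id; columns: city, year, total_reads

    REQUIRED = ("city", "year", "total_reads")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        if (self.frame["total_reads"] <= 0).any():
            bad = self.frame.index[self.frame["total_reads"] <= 0].tolist()
            raise ValidationError(f"non-positive total_reads for samples: {bad[:5]}")

    @classmethod
    def read_csv(cls, path) -> "SampleMetadata":
        frame = pd.read_csv(path, dtype={"city": str})
        if "sample_id" not in frame.columns:
            raise ValidationError(f"{path}: metadata CSV needs a sample_id column")
        return cls(frame.set_index("sample_id"))

    def write_csv(self, path) -> None:
        self.frame.rename_axis("sample_id").to_csv(path)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        """Strict join check: every table sample must have a metadata row."""
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(
                f"{len(missing)} samples lack metadata rows: {missing[:10]}"
            )

    def group_label(self) -> pd.Series:
        """(city, year) group membership per sample."""
        return pd.Series(
            list(zip(self.frame["city"].astype(str), self.frame["year"].astype(str))),
            index=self.frame.index,
        )

    def total_reads(self, sample_ids: Sequence[str]) -> np.ndarray:
        self.require_samples(sample_ids)
        return self.frame.loc[list(sample_ids), "total_reads"].to_numpy(float)


@dataclass
class CityCovariates:
    """Per-city climatic and demographic predictors.

    Columns: ``min_temp`` / ``max_temp`` (June, degrees C), ``rainfall``
    (June total, mm), ``total_population`` (persons, unit configurable),
    ``population_density`` (persons per km^2).
    """

    frame: pd.DataFrame  # index: city

    REQUIRED = ("min_temp", "max_temp", "rainfall", "total_population", "population_density")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"covariates missing columns: {missing}")
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate city rows in covariates")
        if self.frame[list(self.REQUIRED)].isna().any().any():
            raise ValidationError("missing values in fitted covariates")

    @classmethod
    def read_csv(cls, path) -> "CityCovariates":
        frame = pd.read_csv(path)
        if "city" not in frame.columns:
            raise ValidationError(f"{path}: covariate CSV needs a city column")
        return cls(frame.set_index("city"))

    def write_csv(self, path) -> None:
        self.frame.rename_axis("city").to_csv(path)

    def design_matrix(self, cities: Sequence[str]) -> np.ndarray:
        """Intercept-prepended predictor rows for the given cities."""
        x = self.frame.loc[list(cities), list(self.REQUIRED)].to_numpy(float)
        return np.column_stack([np.ones(len(x)), x])


@dataclass(frozen=True)
class StratumKey:
    """One of the kingdom-category x taxonomic-level data strata.

    ``source`` records read- vs assembly-derived provenance; ``categories``
    is a nonempty subset of the kingdom categories; ``level`` the aggregation
    rank ("otu" keeps rows as they are).
    """

    source: str = "reads"
    categories: frozenset = field(default_factory=lambda: frozenset(CATEGORY_KINGDOMS))
    level: str = "otu"

    def __post_init__(self) -> None:
        if self.source not in ("reads", "assembly"):
            raise ValidationError(f"unknown source {self.source!r}")
        cats = frozenset(self.categories)
        if not cats:
            raise ValidationError("categories must be nonempty")
        unknown = cats - set(CATEGORY_KINGDOMS)
        if unknown:
            raise ValidationError(f"unknown categories: {sorted(unknown)}")
        object.__setattr__(self, "categories", cats)
        if self.level not in LEVELS:
            raise ValidationError(f"level must be one of {LEVELS}, got {self.level!r}")


def _kingdom_allowed(kingdom: str, categories: frozenset) -> bool:
    allowed: set[str] = set()
    for cat in categories:
        allowed |= CATEGORY_KINGDOMS[cat]
    return kingdom in allowed


def aggregate_to_level(table: AbundanceTable, level: str) -> AbundanceTable:
    """Sum counts of all OTUs sharing the taxon label at ``level``.

    The new row id is ``"<level>:<label>"``; OTUs unclassified at that rank
    are grouped under ``"<level>:unclassified:<parent>"`` where the parent is
    the nearest classified coarser rank, so no counts are dropped.
    """
    if level == "otu":
        return table
    rank_idx = RANKS.index(level)
    groups: dict[str, list[int]] = {}
    group_lineage: dict[str, tuple[str, ...]] = {}
    for i, otu in enumerate(table.otu_ids):
        lin = table.lineages[otu]
        label = lin[rank_idx]
        if label == UNCLASSIFIED:
            parent = "root"
            for k in range(rank_idx - 1, -1, -1):
                if lin[k] != UNCLASSIFIED:
                    parent = lin[k]
                    break
            row_id = f"{level}:unclassified:{parent}"
            lineage = lin[: rank_idx] + (UNCLASSIFIED,) * (len(RANKS) - rank_idx)
        else:
            row_id = f"{level}:{label}"
            lineage = lin[: rank_idx + 1] + (UNCLASSIFIED,) * (len(RANKS) - rank_idx - 1)
        groups.setdefault(row_id, []).append(i)
        group_lineage.setdefault(row_id, lineage)
    row_ids = sorted(groups)
    counts = np.vstack([table.counts[groups[r]].sum(axis=0) for r in row_ids]) if row_ids else np.zeros((0, table.n_samples), dtype=np.int64)
    return AbundanceTable(
        otu_ids=row_ids,
        lineages={r: group_lineage[r] for r in row_ids},
        counts=counts,
        sample_ids=list(table.sample_ids),
    )


def split_by_stratum(table: AbundanceTable, key: StratumKey) -> AbundanceTable:
    """Restrict to the kingdoms of ``key.categories`` and aggregate to ``key.level``."""
    keep = [o for o in table.otu_ids if _kingdom_allowed(table.lineages[o][0], key.categories)]
    if not keep:
        logger.warning("stratum %s selects no OTUs; returning empty table", key)
        return AbundanceTable([], {}, np.zeros((0, table.n_samples), dtype=np.int64), list(table.sample_ids))
    sub = table.subset_otus(keep)
    return aggregate_to_level(sub, key.level)


def observed_richness(table: AbundanceTable) -> dict[str, int]:
    """Alpha-diversity richness: number of OTUs with count > 0, per sample."""
    present = (table.counts > 0).sum(axis=0)
    return {s: int(present[j]) for j, s in enumerate(table.sample_ids)}
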