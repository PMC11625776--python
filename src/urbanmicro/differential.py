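"""Pairwise differential-abundance screening across city-year groups.

For every unordered pair of (city, year) groups and every taxon (at the OTU
level or aggregated to a coarser rank) whose count total is positive in both
groups, the requested count models are fitted with a group-dummy design and
library-size offset.  Wald p-values of the group coefficient are adjusted by
the Benjamini-Hochberg step-up rule within each (model, pair) family pooling
all taxonomic levels, the per-(taxon, pair) model is arbitrated by smallest
AIC, and taxa that remain significant in many pairs ("most differential",
default at least 11) form the final selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .count_models import MODELS, CountData, compare_by_aic, fit
from .data import AbundanceTable, SampleMetadata, aggregate_to_level

logger = logging.getLogger(__name__)


class PairKey(NamedTuple):
    """Canonicalized unordered pair of (city, year) groups."""

    group_a: tuple[str, str]
    group_b: tuple[str, str]

    @classmethod
    def make(cls, g1: tuple[str, str], g2: tuple[str, str]) -> "PairKey":
        if g1 == g2:
            raise ValueError("a pair needs two distinct (city, year) groups")
        a, b = sorted([tuple(map(str, g1)), tuple(map(str, g2))])
        return cls(a, b)

    def __str__(self) -> str:
        return f"{self.group_a[0]}-{self.group_a[1]}|{self.group_b[0]}-{self.group_b[1]}"


@dataclass
class DifferentialResult:
    """All per-(taxon, pair, model) records plus derived selections.

    ``records`` columns: unit, level, pair, model, raw_p, adj_p, aic,
    converged.  ``chosen_model`` maps (unit, pair) to the AIC-winning model.
    """

    records: pd.DataFrame
    chosen_model: dict[tuple[str, PairKey], str] = field(default_factory=dict)
    family_scope: str = "model-pair"

    def chosen_records(self) -> pd.DataFrame:
        """Rows of ``records`` corresponding to the AIC-chosen model per (unit, pair)."""
        if not len(self.records):
            return self.records
        key = pd.MultiIndex.from_arrays(
            [self.records["unit"], self.records["pair"], self.records["model"]]
        )
        wanted = {(u, p, m) for (u, p), m in self.chosen_model.items()}
        return self.records[[k in wanted for k in key]]

    def differential_pair_count(self, alpha: float = 0.05) -> dict[str, int]:
        """Per taxon, the number of pairs with chosen-model adj_p <= alpha."""
        chosen = self.chosen_records()
        if not len(chosen):
            return {}
        hits = chosen[chosen["adj_p"] <= alpha]
        return hits.groupby("unit")["pair"].nunique().to_dict()


def enumerate_pairs(metadata: SampleMetadata, min_samples: int = 2) -> list[PairKey]:
    """All unordered pairs of (city, year) groups with >= ``min_samples`` each."""
    sizes = metadata.group_label().value_counts()
    usable = sorted(g for g, n in sizes.items() if n >= min_samples)
    skipped = [g for g, n in sizes.items() if n < min_samples]
    for g in skipped:
        logger.warning("group %s has < %d samples; excluded from all pairs", g, min_samples)
    return [
        PairKey.make(usable[i], usable[j])
        for i in range(len(usable))
        for j in range(i + 1, len(usable))
    ]


def pair_mask(table: AbundanceTable, pair: PairKey, otu: str, metadata: SampleMetadata) -> bool:
    """True iff the taxon's total count is positive in both groups of the pair."""
    if otu not in table.otu_ids:
        raise KeyError(otu)
    groups = metadata.group_label()
    row = table.counts[table.otu_ids.index(otu)]
    for group in (pair.group_a, pair.group_b):
        members = [s for s in table.sample_ids if tuple(groups.get(s, ("", ""))) == group]
        if not members:
            return False
        cols = [table.sample_ids.index(s) for s in members]
        if row[cols].sum() <= 0:
            return False
    return True


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Sorting the m p-values ascending as p_(1) <= ... <= p_(m), the adjusted
    value of the i-th is ``min(1, min_{j >= i} m * p_(j) / j)``; output is
    aligned to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def _group_design(
    table: AbundanceTable, metadata: SampleMetadata, pair: PairKey
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Samples of the two groups, their intercept+dummy design, and offsets."""
    groups = metadata.group_label()
    samples = [
        s
        for s in table.sample_ids
        if s in groups.index and tuple(groups[s]) in (pair.group_a, pair.group_b)
    ]
    dummy = np.array([1.0 if tuple(groups[s]) == pair.group_b else 0.0 for s in samples])
    design = np.column_stack([np.ones(len(samples)), dummy])
    offset = np.log(metadata.total_reads(samples))
    return samples, design, offset


def run_pairwise(
    table: AbundanceTable,
    metadata: SampleMetadata,
    models: Sequence[str] = MODELS,
    levels: Sequence[str] = ("otu",),
    min_samples: int = 2,
    family_scope: str = "model-pair",
) -> DifferentialResult:
    """Fit all requested models for every (level, pair, taxon) combination.

    The raw p-value recorded per fit is the two-sided Wald test of the
    count-part group coefficient.  BH adjustment pools, per (model, pair),
    the tests of all taxa across the requested levels (``family_scope``
    alternatives: "model-pair-level", "global").
    """
    bad = set(models) - set(MODELS)
    if bad:
        raise ValueError(f"unknown models: {sorted(bad)}")
    if family_scope not in ("model-pair", "model-pair-level", "global"):
        raise ValueError(f"unknown family_scope {family_scope!r}")
    metadata.require_samples(table.sample_ids)
    pairs = enumerate_pairs(metadata, min_samples=min_samples)
    groups = metadata.group_label()

    rows = []
    n_failed = 0
    for level in levels:
        level_table = aggregate_to_level(table, level)
        counts_df = level_table.to_frame()
        for pair in pairs:
            samples, design, offset = _group_design(level_table, metadata, pair)
            if not samples:
                continue
            sub = counts_df[samples]
            in_b = np.array([tuple(groups[s]) == pair.group_b for s in samples])
            tot_a = sub.loc[:, ~in_b].sum(axis=1)
            tot_b = sub.loc[:, in_b].sum(axis=1)
            units = sub.index[(tot_a > 0) & (tot_b > 0)]
            for unit in units:
                y = sub.loc[unit].to_numpy()
                data = CountData(y=y, design_count=design, offset=offset)
                for model in models:
                    try:
                        f = fit(model, data)
                    except Exception:
                        n_failed += 1
                        continue
                    raw_p = f.group_pvalue if f.se_available else np.nan
                    rows.append(
                        {
                            "unit": unit,
                            "level": level,
                            "pair": pair,
                            "model": model,
                            "raw_p": raw_p,
                            "aic": f.aic,
                            "converged": f.converged,
                            "n_params": f.n_params,
                        }
                    )
    if n_failed:
        logger.warning("%d model fits failed and were skipped", n_failed)

    records = pd.DataFrame(
        rows, columns=["unit", "level", "pair", "model", "raw_p", "aic", "converged", "n_params"]
    )
    records["adj_p"] = np.nan
    if len(records):
        testable = records["raw_p"].notna()
        if family_scope == "global":
            keys = [()] * len(records)
        elif family_scope == "model-pair":
            keys = list(zip(records["model"], records["pair"]))
        else:
            keys = list(zip(records["model"], records["pair"], records["level"]))
        records["_family"] = pd.Series(keys, index=records.index).astype(str)
        for _, idx in records.loc[testable].groupby("_family").groups.items():
            records.loc[idx, "adj_p"] = bh_adjust(records.loc[idx, "raw_p"].to_numpy())
        records = records.drop(columns="_family")

    chosen: dict[tuple[str, PairKey], str] = {}
    if len(records):
        conv = records[records["converged"]].copy()
        conv["_order"] = conv["model"].map({m: i for i, m in enumerate(MODELS)})
        for (unit, pair), grp in conv.groupby(["unit", "pair"], sort=False):
            best = grp.sort_values(["aic", "n_params", "_order"]).iloc[0]
            chosen[(unit, pair)] = best["model"]
    return DifferentialResult(records=records, chosen_model=chosen, family_scope=family_scope)


def select_top_k(
    result: DifferentialResult, model: str, k: int = 5
) -> tuple[dict[PairKey, list[str]], dict]:
    """Per pair, the k taxa with the lowest adjusted p under ``model``.

    Ties break by AIC, then unit id.  Also returns summary statistics over
    the union: the selected-unit list and the fraction of tested units never
    selected in any pair.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = result.records[(result.records["model"] == model) & result.records["adj_p"].notna()]
    per_pair: dict[PairKey, list[str]] = {}
    for pair, grp in sub.groupby("pair", sort=False):
        ordered = grp.sort_values(["adj_p", "aic", "unit"])
        per_pair[pair] = ordered["unit"].head(k).tolist()
    selected_union = sorted(set().union(*per_pair.values())) if per_pair else []
    tested = sorted(sub["unit"].unique())
    never = [u for u in tested if u not in set(selected_union)]
    summary = {
        "selected_union": selected_union,
        "n_selected": len(selected_union),
        "fraction_never_selected": (len(never) / len(tested)) if tested else 0.0,
    }
    return per_pair, summary


def most_differential(
    result: DifferentialResult, alpha: float = 0.05, min_pairs: int = 11
) -> list[str]:
    """Taxa with chosen-model adj_p <= alpha in at least ``min_pairs`` pairs.

    The default of 11 corresponds to "differential in more than ten
    year-city comparisons".
    """
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    counts = result.differential_pair_count(alpha=alpha)
    return sorted(u for u, c in counts.items() if c >= min_pairs)
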