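"""Condition-versus-condition fold changes and direction classification.

A taxon's imbalance between two conditions is summarised by the ratio of its
mean relative abundances after adding a small pseudocount,

    f = (mean_a + eps) / (mean_b + eps),      fold = max(f, 1/f),

and classified as increased in one condition when fold strictly exceeds the
threshold (default 1.5), else unchanged.  No hypothesis testing is attached:
the classification is purely threshold-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .table import AGGREGATION_RANKS, RelativeAbundanceTable

INCREASED_IN_A = "increased_in_a"
INCREASED_IN_B = "increased_in_b"
UNCHANGED = "unchanged"

DEFAULT_FOLD_THRESHOLD = 1.5
DEFAULT_PSEUDOCOUNT = 1e-6
DEFAULT_TOP_K = 15


@dataclass(frozen=True)
class DifferentialRecord:
    """One taxon's fold change between two conditions at one rank."""

    taxon: str
    rank: str
    condition_a: str
    condition_b: str
    mean_a: float
    mean_b: float
    fold: float
    direction: str


@dataclass(frozen=True)
class AbundantFamilySet:
    """Top-k families of one condition, ordered by mean relative abundance."""

    condition: str
    families: tuple[str, ...]
    k: int


def condition_means(table: RelativeAbundanceTable, condition: str) -> pd.Series:
    """Per-taxon arithmetic mean relative abundance over one condition."""
    samples = table.samples_with_condition(condition)
    if not samples:
        known = sorted(table.metadata["condition"].unique())
        raise ValueError(f"no samples with condition {condition!r} (known: {known})")
    return table.values[samples].mean(axis=1)


def fold_change(mean_a: float, mean_b: float,
                pseudocount: float = DEFAULT_PSEUDOCOUNT,
                threshold: float = DEFAULT_FOLD_THRESHOLD) -> tuple[float, str]:
    """Fold >= 1 and direction class for a pair of condition means.

    Antisymmetric: swapping the means preserves the fold and mirrors the
    direction.  The threshold is strict — fold exactly at the threshold is
    classified unchanged.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    f = (mean_a + pseudocount) / (mean_b + pseudocount)
    fold = max(f, 1.0 / f)
    if fold <= threshold:
        return fold, UNCHANGED
    return fold, INCREASED_IN_A if f > 1 else INCREASED_IN_B


def differential_table(table: RelativeAbundanceTable, condition_a: str,
                       condition_b: str, rank: str = "family",
                       threshold: float = DEFAULT_FOLD_THRESHOLD,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT,
                       central: str = "mean") -> list[DifferentialRecord]:
    """One :class:`DifferentialRecord` per taxon at ``rank``, sorted by label.

    ``central`` selects the per-condition summary of relative abundance:
    arithmetic ``mean`` (default) or ``median``.
    """
    if rank not in AGGREGATION_RANKS:
        raise ValueError(f"rank must be one of {AGGREGATION_RANKS}, got {rank!r}")
    if central not in ("mean", "median"):
        raise ValueError("central must be 'mean' or 'median'")
    at_rank = table.aggregate_to_rank(rank)
    samples_a = at_rank.samples_with_condition(condition_a)
    samples_b = at_rank.samples_with_condition(condition_b)
    for cond, samples in ((condition_a, samples_a), (condition_b, samples_b)):
        if not samples:
            raise ValueError(f"no samples with condition {cond!r}")
    agg = "mean" if central == "mean" else "median"
    means_a = getattr(at_rank.values[samples_a], agg)(axis=1)
    means_b = getattr(at_rank.values[samples_b], agg)(axis=1)
    records = []
    for taxon in sorted(at_rank.taxon_ids):
        ma, mb = float(means_a[taxon]), float(means_b[taxon])
        fold, direction = fold_change(ma, mb, pseudocount, threshold)
        records.append(DifferentialRecord(taxon, rank, condition_a, condition_b,
                                          ma, mb, fold, direction))
    return records


def top_abundant_families(table: RelativeAbundanceTable, condition: str,
                          k: int = DEFAULT_TOP_K) -> AbundantFamilySet:
    """Top-k families by mean relative abundance in one condition.

    Ties are broken lexicographically by family label so the set is
    deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    at_family = table.aggregate_to_rank("family")
    means = condition_means(at_family, condition)
    ordered = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    return AbundantFamilySet(condition, tuple(t for t, _ in ordered[:k]), k)


def records_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def write_differential_tsv(records: Sequence[DifferentialRecord],
                           path: str | Path,
                           header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        records_frame(records).to_csv(fh, sep="\t", index=False)
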