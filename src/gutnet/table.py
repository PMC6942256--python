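"""Lineage-annotated abundance tables: parsing, writing, aggregation, merging.

The count matrix is held taxa-in-rows, samples-in-columns throughout the
package.  Per-sample metadata (study id and clinical condition) travels with
the counts so downstream stages never need a second lookup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lineage import (
    RANK_NAMES,
    RANKS,
    UNCLASSIFIED,
    TaxonLineage,
    format_lineage,
    lineage_from_labels,
    parse_lineage,
)

AGGREGATION_RANKS = ("phylum", "class", "family")
CONDITIONS = ("CD", "UC", "healthy", "other")

METADATA_COLUMNS = ("study_id", "condition")


class TableFormatError(ValueError):
    """Raised when an abundance or metadata file violates the format."""


def _check_common(counts: pd.DataFrame, lineages: Sequence[TaxonLineage],
                  metadata: pd.DataFrame) -> pd.DataFrame:
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon ids: {dup}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    if len(lineages) != counts.shape[0]:
        raise ValueError("one lineage per taxon required "
                         f"({len(lineages)} lineages, {counts.shape[0]} taxa)")
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if set(metadata.index) != set(counts.columns):
        extra = sorted(set(metadata.index) - set(counts.columns))
        absent = sorted(set(counts.columns) - set(metadata.index))
        raise ValueError("metadata must cover exactly the sample ids "
                         f"(unmatched metadata rows: {extra}; samples without "
                         f"metadata: {absent})")
    return metadata.loc[counts.columns]


@dataclass
class AbundanceTable:
    """Taxa x samples count matrix with lineages and sample metadata.

    Parameters
    ----------
    counts : DataFrame
        Non-negative counts, index = taxon ids, columns = sample ids.
    lineages : list of TaxonLineage
        Aligned with ``counts.index``.
    metadata : DataFrame
        Indexed by sample id with columns ``study_id`` and ``condition``.
    """

    counts: pd.DataFrame
    lineages: list[TaxonLineage]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.metadata = _check_common(self.counts, self.lineages, self.metadata)
        values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise ValueError("negative counts are not allowed")
        totals = self.counts.sum(axis=0)
        empty = totals.index[totals <= 0].tolist()
        if empty:
            raise ValueError(f"samples with zero total count: {empty}")

    # -- basic accessors -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def lineage_of(self, taxon_id: str) -> TaxonLineage:
        return self.lineages[self.counts.index.get_loc(taxon_id)]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_with_condition(self, condition: str) -> list[str]:
        return list(self.metadata.index[self.metadata["condition"] == condition])

    def equals(self, other: "AbundanceTable") -> bool:
        return (self.counts.equals(other.counts)
                and [l.labels for l in self.lineages] == [l.labels for l in other.lineages]
                and self.metadata.equals(other.metadata))

    # -- transformations -------------------------------------------------
    def aggregate_to_rank(self, rank: str) -> "AbundanceTable":
        """Sum counts over taxa sharing the label at ``rank``.

        Output taxon ids are the distinct rank labels (including the
        ``unclassified`` pool); per-sample totals are conserved exactly.
        """
        if rank not in AGGREGATION_RANKS:
            raise ValueError(f"rank must be one of {AGGREGATION_RANKS}, got {rank!r}")
        if self.n_taxa == 0:
            raise ValueError("cannot aggregate an empty table")
        labels = [lin.get(rank) for lin in self.lineages]
        grouped = self.counts.groupby(pd.Index(labels, name="taxon"), sort=True).sum()
        # Label identity defines the aggregated taxon; when one label occurs
        # under several upper lineages, keep the lexicographically smallest.
        by_label: dict[str, TaxonLineage] = {}
        for label, lin in zip(labels, self.lineages):
            cand = lin.truncate(rank)
            if label not in by_label or cand.labels < by_label[label].labels:
                by_label[label] = cand
        lineages = [by_label[label] for label in grouped.index]
        return AbundanceTable(grouped, lineages, self.metadata.copy())

    def to_relative(self) -> "RelativeAbundanceTable":
        """Per-sample proportions (each sample column sums to one)."""
        totals = self.counts.sum(axis=0)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"zero-total samples cannot be normalised: {bad}")
        values = self.counts.astype(float).div(totals, axis=1)
        return RelativeAbundanceTable(values, list(self.lineages), self.metadata.copy())


@dataclass
class RelativeAbundanceTable:
    """Same layout as :class:`AbundanceTable` but values are proportions."""

    values: pd.DataFrame
    lineages: list[TaxonLineage]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.metadata = _check_common(self.values, self.lineages, self.metadata)
        arr = self.values.to_numpy()
        if arr.size:
            if arr.min() < 0 or arr.max() > 1 + 1e-12:
                raise ValueError("relative abundances must lie in [0, 1]")
            sums = arr.sum(axis=0)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValueError("sample proportions must sum to 1 within 1e-9")

    taxon_ids = AbundanceTable.taxon_ids
    sample_ids = AbundanceTable.sample_ids
    lineage_of = AbundanceTable.lineage_of
    samples_with_condition = AbundanceTable.samples_with_condition

    @property
    def counts(self) -> pd.DataFrame:  # shared accessor name for helpers
        return self.values

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def aggregate_to_rank(self, rank: str) -> "RelativeAbundanceTable":
        """Sum proportions over taxa sharing the label at ``rank``."""
        if rank not in AGGREGATION_RANKS:
            raise ValueError(f"rank must be one of {AGGREGATION_RANKS}, got {rank!r}")
        if self.n_taxa == 0:
            raise ValueError("cannot aggregate an empty table")
        labels = [lin.get(rank) for lin in self.lineages]
        grouped = self.values.groupby(pd.Index(labels, name="taxon"), sort=True).sum()
        by_label: dict[str, TaxonLineage] = {}
        for label, lin in zip(labels, self.lineages):
            cand = lin.truncate(rank)
            if label not in by_label or cand.labels < by_label[label].labels:
                by_label[label] = cand
        lineages = [by_label[label] for label in grouped.index]
        return RelativeAbundanceTable(grouped, lineages, self.metadata.copy())


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------

def default_metadata(sample_ids: Iterable[str], study_id: str = "unknown",
                     condition: str = "other") -> pd.DataFrame:
    """Placeholder metadata for tables read without a metadata file."""
    ids = list(sample_ids)
    return pd.DataFrame({"study_id": study_id, "condition": condition},
                        index=pd.Index(ids, name="sample_id"))


def parse_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, study_id, condition)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ("sample_id",) + METADATA_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: metadata missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableFormatError(f"{path}: duplicate sample ids in metadata: {dup}")
    return df.set_index("sample_id")[list(METADATA_COLUMNS)]


def write_metadata(metadata: pd.DataFrame, path: str | Path,
                   header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("sample_id\tstudy_id\tcondition\n")
        for sid, row in metadata.iterrows():
            fh.write(f"{sid}\t{row['study_id']}\t{row['condition']}\n")


def _parse_count(token: str, path, lineno: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise TableFormatError(
            f"{path}, line {lineno}: malformed count {token!r}") from None
    if not math.isfinite(value):
        raise TableFormatError(f"{path}, line {lineno}: non-finite count {token!r}")
    if value < 0:
        raise TableFormatError(f"{path}, line {lineno}: negative count {token!r}")
    return value


def parse_abundance_table(path: str | Path, dialect: str = "prefix",
                          metadata: pd.DataFrame | str | Path | None = None,
                          ) -> AbundanceTable:
    """Read a TSV abundance table.

    ``prefix`` / ``silva`` dialects expect columns
    ``taxon_id <TAB> lineage <TAB> sample ...``; ``plain`` expects the six
    rank labels as separate columns after the taxon id.  A BIOM classic TSV
    whose header starts with ``#OTU ID`` (optionally with a trailing
    ``taxonomy`` column) is accepted under ``dialect="plain"``.

    Samples whose total count is zero are rejected.  ``metadata`` may be a
    DataFrame, a path to a metadata TSV, or None (placeholder metadata).
    """
    if dialect not in ("prefix", "silva", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = fh.read().splitlines()

    header = None
    header_line = 0
    rows: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(raw, start=1):
        if not line.strip():
            continue
        if line.startswith("#") and not line.startswith("#OTU ID"):
            continue
        if header is None:
            header = line.split("\t")
            header_line = lineno
        else:
            rows.append((lineno, line.split("\t")))
    if header is None:
        raise TableFormatError(f"{path}: no header row found")

    biom = header[0] == "#OTU ID"
    taxonomy_last = biom and header[-1].strip().lower() == "taxonomy"
    if biom:
        sample_ids = header[1:-1] if taxonomy_last else header[1:]
        n_lineage_cols = 0
    elif dialect == "plain":
        expected = ["taxon_id", *RANK_NAMES]
        if [h.strip() for h in header[:7]] != expected:
            raise TableFormatError(
                f"{path}, line {header_line}: plain dialect header must start "
                f"with {expected}")
        sample_ids = header[7:]
        n_lineage_cols = 6
    else:
        sample_ids = header[2:]
        n_lineage_cols = 1
    if not sample_ids:
        raise TableFormatError(f"{path}, line {header_line}: no sample columns")
    seen = set()
    for sid in sample_ids:
        if sid in seen:
            raise TableFormatError(
                f"{path}, line {header_line}: duplicate sample id {sid!r}")
        seen.add(sid)

    n_fixed = 1 + n_lineage_cols
    taxon_ids: list[str] = []
    lineages: list[TaxonLineage] = []
    data: list[list[float]] = []
    for lineno, fields in rows:
        expected_len = n_fixed + len(sample_ids) + (1 if taxonomy_last else 0)
        if len(fields) != expected_len:
            raise TableFormatError(
                f"{path}, line {lineno}: expected {expected_len} columns, "
                f"found {len(fields)}")
        taxon_id = fields[0].strip()
        if not taxon_id:
            raise TableFormatError(f"{path}, line {lineno}: empty taxon id")
        if biom:
            if taxonomy_last:
                text = fields[-1]
                lin = parse_lineage(text, "prefix" if "__" in text else "silva")
            else:
                lin = lineage_from_labels()
            counts = fields[1:-1] if taxonomy_last else fields[1:]
        elif dialect == "plain":
            lin = lineage_from_labels(**dict(zip(RANK_NAMES, fields[1:7])))
            counts = fields[7:]
        else:
            lin = parse_lineage(fields[1], dialect)
            counts = fields[2:]
        taxon_ids.append(taxon_id)
        lineages.append(lin)
        data.append([_parse_count(t, path, lineno) for t in counts])

    if not taxon_ids:
        raise TableFormatError(f"{path}: table has no taxon rows")
    arr = np.asarray(data)
    if np.allclose(arr, np.round(arr)):
        arr = np.round(arr).astype(np.int64)
    counts = pd.DataFrame(arr, index=pd.Index(taxon_ids, name="taxon"),
                          columns=sample_ids)
    if isinstance(metadata, (str, Path)):
        metadata = parse_metadata(metadata)
    if metadata is None:
        metadata = default_metadata(sample_ids)
    return AbundanceTable(counts, lineages, metadata)


def write_abundance_table(table: AbundanceTable | RelativeAbundanceTable,
                          path: str | Path, dialect: str = "prefix",
                          header_comment: str | None = None) -> None:
    """Write a table in the given dialect (UTF-8, tab-separated)."""
    if dialect not in ("prefix", "silva", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    matrix = table.counts if isinstance(table, AbundanceTable) else table.values
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        if dialect == "plain":
            fixed = ["taxon_id", *RANK_NAMES]
        else:
            fixed = ["taxon_id", "lineage"]
        fh.write("\t".join(fixed + list(matrix.columns)) + "\n")
        for taxon_id, lin in zip(matrix.index, table.lineages):
            row = matrix.loc[taxon_id]
            values = "\t".join(_format_number(v) for v in row.to_numpy())
            if dialect == "plain":
                fh.write("\t".join([taxon_id, *lin.labels]) + "\t" + values + "\n")
            else:
                fh.write(f"{taxon_id}\t{format_lineage(lin, dialect)}\t{values}\n")


def _format_number(v) -> str:
    if float(v) == int(v):
        return str(int(v))
    return repr(float(v))


# ---------------------------------------------------------------------------
# Multi-study merging
# ---------------------------------------------------------------------------

def merge_studies(tables: Sequence[AbundanceTable]) -> AbundanceTable:
    """Union taxa across studies; sample ids become ``study_id:sample_id``.

    Missing taxon x sample cells are filled with zero.  Taxon identity is the
    taxon id (at aggregated ranks, the rank label); the same id carrying two
    different lineages is an error.
    """
    if not tables:
        raise ValueError("no tables to merge")
    lineage_by_taxon: dict[str, TaxonLineage] = {}
    frames = []
    meta_rows = []
    seen_samples: set[str] = set()
    for table in tables:
        for taxon_id, lin in zip(table.taxon_ids, table.lineages):
            prev = lineage_by_taxon.get(taxon_id)
            if prev is None:
                lineage_by_taxon[taxon_id] = lin
            elif prev.labels != lin.labels:
                raise ValueError(
                    f"taxon {taxon_id!r} has conflicting lineages across studies")
        new_ids = [f"{table.metadata.loc[s, 'study_id']}:{s}" for s in table.sample_ids]
        for sid in new_ids:
            if sid in seen_samples:
                raise ValueError(f"sample id collision after study prefixing: {sid!r}")
            seen_samples.add(sid)
        frame = table.counts.copy()
        frame.columns = new_ids
        frames.append(frame)
        meta = table.metadata.copy()
        meta.index = pd.Index(new_ids, name="sample_id")
        meta_rows.append(meta)

    all_taxa = sorted(lineage_by_taxon)
    merged = pd.concat([f.reindex(all_taxa) for f in frames], axis=1).fillna(0)
    if all(np.issubdtype(f.dtypes.iloc[0], np.integer) for f in frames):
        merged = merged.astype(np.int64)
    merged.index.name = "taxon"
    metadata = pd.concat(meta_rows)
    return AbundanceTable(merged, [lineage_by_taxon[t] for t in all_taxa], metadata)
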