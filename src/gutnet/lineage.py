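"""Ranked taxonomy lineages parsed from annotation strings.

Three string dialects are supported:

``prefix``
    Greengenes/QIIME style, e.g. ``k__Bacteria;p__Firmicutes;f__Lachnospiraceae``.
    Rank is carried by the one-letter prefix; missing ranks become the
    ``unclassified`` sentinel.
``silva``
    Positional, e.g. ``Bacteria;Firmicutes;Clostridia;Clostridiales;...``;
    tokens are assigned kingdom -> genus in order.
``plain``
    No lineage string at all: the six ranks arrive as separate table columns
    (see :mod:`gutnet.table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

RANKS = ("kingdom", "phylum", "class_", "order", "family", "genus")
#: column / CLI-facing names (``class`` without the keyword-escaping underscore)
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIXES = ("k", "p", "c", "o", "f", "g")
UNCLASSIFIED = "unclassified"

_PREFIX_TO_RANK = dict(zip(RANK_PREFIXES, RANKS))


def _clean(label: str | None) -> str:
    label = (label or "").strip()
    return label if label else UNCLASSIFIED


@dataclass(frozen=True)
class TaxonLineage:
    """One taxon's ranked labels, kingdom through genus.

    Unknown ranks hold the sentinel ``"unclassified"``.  ``source_string``
    keeps the raw annotation as read and is excluded from equality: two
    lineages are equal iff their six rank labels are equal.
    """

    kingdom: str = UNCLASSIFIED
    phylum: str = UNCLASSIFIED
    class_: str = UNCLASSIFIED
    order: str = UNCLASSIFIED
    family: str = UNCLASSIFIED
    genus: str = UNCLASSIFIED
    source_string: str = field(default="", compare=False)

    def get(self, rank: str) -> str:
        """Label at ``rank`` (accepts both ``class`` and ``class_``)."""
        if rank == "class":
            rank = "class_"
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANK_NAMES}")
        return getattr(self, rank)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(getattr(self, r) for r in RANKS)

    def truncate(self, rank: str) -> "TaxonLineage":
        """Lineage with every rank below ``rank`` reset to unclassified."""
        if rank == "class":
            rank = "class_"
        keep = RANKS.index(rank) + 1
        labels = self.labels[:keep] + (UNCLASSIFIED,) * (len(RANKS) - keep)
        lin = TaxonLineage(*labels)
        return TaxonLineage(*labels, source_string=format_lineage(lin, "prefix"))

    def is_classified_at(self, rank: str) -> bool:
        return self.get(rank) != UNCLASSIFIED


def parse_lineage(text: str, dialect: str = "prefix") -> TaxonLineage:
    """Parse one lineage annotation string into a :class:`TaxonLineage`."""
    if dialect == "prefix":
        labels = {r: UNCLASSIFIED for r in RANKS}
        for token in text.split(";"):
            token = token.strip()
            if not token:
                continue
            if "__" in token:
                code, _, label = token.partition("__")
                rank = _PREFIX_TO_RANK.get(code.strip().lower())
                if rank is not None:  # ignore ranks we do not track (e.g. s__)
                    labels[rank] = _clean(label)
            # bare tokens without a prefix are ignored in this dialect
        return TaxonLineage(**labels, source_string=text)
    if dialect == "silva":
        tokens = [t.strip() for t in text.split(";")]
        labels = [_clean(tokens[i]) if i < len(tokens) else UNCLASSIFIED
                  for i in range(len(RANKS))]
        return TaxonLineage(*labels, source_string=text)
    raise ValueError(f"unknown lineage dialect {dialect!r}")


def format_lineage(lineage: TaxonLineage, dialect: str = "prefix") -> str:
    """Canonical annotation string for ``lineage`` in ``dialect``."""
    if dialect == "prefix":
        return ";".join(f"{c}__{l}" for c, l in zip(RANK_PREFIXES, lineage.labels))
    if dialect == "silva":
        return ";".join(lineage.labels)
    raise ValueError(f"unknown lineage dialect {dialect!r}")


def lineage_from_labels(**labels: str) -> TaxonLineage:
    """Build a lineage from keyword rank labels, canonicalising the source."""
    clean = {r: _clean(labels.get(n, labels.get(r, ""))) for r, n in zip(RANKS, RANK_NAMES)}
    lin = TaxonLineage(**clean)
    return TaxonLineage(**clean, source_string=format_lineage(lin, "prefix"))
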