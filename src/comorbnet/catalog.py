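"""Disease gene catalogs.

Loading, normalising, merging and comparing candidate-gene lists compiled
from multiple evidence sources (core literature genes, computationally
prioritized genes, association-study hits). Symbols are HGNC-style tokens;
normalisation is deliberately limited to trimming and uppercasing — no
alias or cross-identifier mapping is attempted, so results are a
deterministic function of the input lists.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import EmptyInputError, MalformedRecordError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "OverlapReport",
    "normalize_symbol",
    "load_gene_list",
    "merge_sources",
    "compare_sets",
    "write_gene_list",
    "write_overlap_report",
]


def normalize_symbol(raw: str, *, context: str = "") -> str:
    """Normalise a raw gene symbol: strip whitespace, uppercase.

    Raises
    ------
    MalformedRecordError
        If the symbol is empty after stripping, or contains internal
        tabs/newlines (a sign of a mis-split record).
    """
    sym = raw.strip().upper()
    where = f" ({context})" if context else ""
    if not sym:
        raise MalformedRecordError(f"empty gene symbol{where}")
    if any(c in sym for c in "\t\n\r"):
        raise MalformedRecordError(f"gene symbol contains tab/newline{where}: {raw!r}")
    return sym


@dataclass(frozen=True)
class GeneSet:
    """A named, source-tagged set of normalised gene symbols for one disease.

    ``provenance`` maps a source tag to the subset of ``members`` that source
    contributed; downstream analysis uses only the union, but the breakdown
    is kept for reporting.
    """

    name: str
    members: frozenset[str]
    disease_label: str = ""
    source_tags: frozenset[str] = frozenset()
    provenance: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise EmptyInputError(f"gene set {self.name!r} has no members")
        for m in self.members:
            if not m or m != m.strip().upper() or any(c in m for c in "\t\n\r"):
                raise MalformedRecordError(
                    f"gene set {self.name!r} contains unnormalised symbol {m!r}"
                )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class OverlapReport:
    """Partition of two gene sets into A-only / shared / B-only."""

    name_a: str
    name_b: str
    a_only: frozenset[str]
    b_only: frozenset[str]
    shared: frozenset[str]

    def __post_init__(self) -> None:
        if self.a_only & self.shared or self.b_only & self.shared or self.a_only & self.b_only:
            raise ValueError("overlap partition is not disjoint")

    @property
    def n_a(self) -> int:
        return len(self.a_only) + len(self.shared)

    @property
    def n_b(self) -> int:
        return len(self.b_only) + len(self.shared)

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def load_gene_list(
    path: str | Path,
    *,
    format: str = "plain",
    column: str | int | None = None,
    name: str | None = None,
    disease_label: str = "",
    source_tag: str | None = None,
) -> GeneSet:
    """Load one gene list from disk into a :class:`GeneSet`.

    Parameters
    ----------
    path
        Input file. ``plain``: one symbol per line, blank lines and lines
        starting with ``#`` ignored. ``tsv``: tab-separated with a header
        row; ``column`` names (or 0-based indexes) the symbol column.
    column
        Required for ``format='tsv'``.

    Duplicate symbols (after normalisation) are collapsed; the number of
    duplicates is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw: list[str] = []
    if format == "plain":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            raw.append(normalize_symbol(stripped, context=f"{path.name}:{lineno}"))
    elif format == "tsv":
        if column is None:
            raise ValueError("format='tsv' requires a symbol column")
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if isinstance(column, int):
            if column >= frame.shape[1]:
                raise MalformedRecordError(
                    f"{path.name}: column index {column} out of range"
                )
            series = frame.iloc[:, column]
        else:
            if column not in frame.columns:
                raise MalformedRecordError(
                    f"{path.name}: no column named {column!r}"
                )
            series = frame[column]
        for i, value in series.items():
            if pd.isna(value):
                raise MalformedRecordError(f"{path.name}: missing symbol in row {i}")
            raw.append(normalize_symbol(str(value), context=f"{path.name} row {i}"))
    else:
        raise ValueError(f"unknown gene list format {format!r}")

    members = frozenset(raw)
    if not members:
        raise EmptyInputError(f"{path}: no gene symbols found")
    n_dup = len(raw) - len(members)
    if n_dup:
        logger.info("%s: collapsed %d duplicate symbol(s)", path.name, n_dup)
    set_name = name if name is not None else path.stem
    tag = source_tag if source_tag is not None else set_name
    return GeneSet(
        name=set_name,
        members=members,
        disease_label=disease_label,
        source_tags=frozenset({tag}),
        provenance={tag: members},
    )


def merge_sources(sets: Sequence[GeneSet], name: str, *, disease_label: str = "") -> GeneSet:
    """Union several evidence-source gene lists into one disease gene set.

    Per-source membership is retained in ``provenance``. Idempotent and
    order-invariant in the member set.
    """
    if not sets:
        raise EmptyInputError("merge_sources requires at least one input set")
    members: set[str] = set()
    tags: set[str] = set()
    provenance: dict[str, frozenset[str]] = {}
    for gs in sets:
        members |= gs.members
        tags |= gs.source_tags
        for tag, contributed in gs.provenance.items():
            provenance[tag] = frozenset(provenance.get(tag, frozenset()) | contributed)
    label = disease_label or next((g.disease_label for g in sets if g.disease_label), "")
    return GeneSet(
        name=name,
        members=frozenset(members),
        disease_label=label,
        source_tags=frozenset(tags),
        provenance=provenance,
    )


def compare_sets(a: GeneSet, b: GeneSet) -> OverlapReport:
    """Partition two disease gene sets into A-only, shared and B-only genes."""
    shared = a.members & b.members
    return OverlapReport(
        name_a=a.name,
        name_b=b.name,
        a_only=frozenset(a.members - shared),
        b_only=frozenset(b.members - shared),
        shared=frozenset(shared),
    )


def write_gene_list(gene_set: GeneSet, path: str | Path) -> None:
    """Write a gene set as a sorted plain-text list (round-trips with
    :func:`load_gene_list`)."""
    path = Path(path)
    lines = [f"# gene set: {gene_set.name} ({len(gene_set)} genes)"]
    lines.extend(gene_set.sorted_members())
    path.write_text("\n".join(lines) + "\n")


def write_overlap_report(report: OverlapReport, path: str | Path) -> None:
    """Write an overlap partition as TSV (columns: gene, category)."""
    rows = (
        [(g, "shared") for g in sorted(report.shared)]
        + [(g, "a_only") for g in sorted(report.a_only)]
        + [(g, "b_only") for g in sorted(report.b_only)]
    )
    frame = pd.DataFrame(rows, columns=["gene", "category"])
    frame.to_csv(path, sep="\t", index=False)


def genes_from_iterable(symbols: Iterable[str], name: str, **kwargs) -> GeneSet:
    """Build a GeneSet from an in-memory iterable of raw symbols."""
    members = frozenset(normalize_symbol(s) for s in symbols)
    if not members:
        raise EmptyInputError(f"gene set {name!r} would be empty")
    return GeneSet(name=name, members=members, **kwargs)
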