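"""Over-representation analysis of gene sets against annotation collections.

The statistic is the classical hypergeometric upper tail: for a tested set
of size ``n`` drawn from a universe of ``N`` genes of which ``K`` belong to
a term, the p-value of an observed overlap ``k`` is

    P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n).

Per collection and per tested set, raw p-values are adjusted across all
tested terms with the Benjamini-Hochberg step-up procedure and gated at a
single alpha (0.01 is the conventional gate for pathway collections here,
0.05 for GO biological process). An EASE-style conservative variant (the
overlap reduced by one before taking the tail, as popularised by DAVID) is
available as an opt-in method.

The background universe defaults to annotation closure — the union of all
term members — which is the most common and most reproducible convention;
an explicit universe can be supplied instead. Tested-set size ``n`` counts
only genes that map into the universe; unmapped genes are logged, never
silently dropped into the margins.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .catalog import GeneSet, normalize_symbol
from .errors import (
    EmptyIntersectionError,
    InvalidCountError,
    MalformedRecordError,
    UnknownTermError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTerm",
    "AnnotationCollection",
    "EnrichmentResult",
    "PathwayComparison",
    "ComparisonRow",
    "TermGeneBreakdown",
    "read_gmt",
    "write_gmt",
    "hypergeometric_pvalue",
    "ease_pvalue",
    "bh_adjust",
    "run_enrichment",
    "compare_enrichments",
    "pathway_gene_breakdown",
    "results_to_frame",
    "write_results",
    "read_results",
]

#: fixed-precision format for p-values in output tables (6 significant digits)
PVALUE_FORMAT = "{:.5e}"


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise MalformedRecordError(f"term {self.term_id!r} has no members")


class AnnotationCollection:
    """A category of annotation terms (e.g. KEGG pathways, GO-BP) plus the
    background universe used for testing."""

    def __init__(
        self,
        category: str,
        terms: Sequence[AnnotationTerm],
        universe: Iterable[str] | None = None,
    ) -> None:
        self.category = category
        self.terms: tuple[AnnotationTerm, ...] = tuple(terms)
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise MalformedRecordError(f"duplicate term id(s): {dup}")
        closure = frozenset().union(*(t.members for t in self.terms)) if self.terms else frozenset()
        if universe is None:
            self.universe: frozenset[str] = closure
        else:
            self.universe = frozenset(universe)
            if not closure <= self.universe:
                missing = sorted(closure - self.universe)[:5]
                raise MalformedRecordError(
                    f"universe does not cover term members (e.g. {missing})"
                )
        self._by_id = {t.term_id: t for t in self.terms}

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> AnnotationTerm:
        try:
            return self._by_id[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term id {term_id!r}") from None

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._by_id


def read_gmt(
    path: str | Path,
    *,
    category: str = "pathway",
    universe: Iterable[str] | None = None,
) -> AnnotationCollection:
    """Read a GMT file (tab-separated: term id, description, member genes).

    Symbols are normalised on load. The universe defaults to the union of
    all term members.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    terms: list[AnnotationTerm] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise MalformedRecordError(
                f"{path.name}:{lineno}: GMT line needs >= 3 tab-separated fields"
            )
        term_id, name = fields[0].strip(), fields[1].strip()
        members = frozenset(
            normalize_symbol(f, context=f"{path.name}:{lineno}")
            for f in fields[2:]
            if f.strip()
        )
        terms.append(AnnotationTerm(term_id=term_id, name=name, members=members))
    return AnnotationCollection(category=category, terms=terms, universe=universe)


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    """Write the collection in GMT format (members sorted; round-trips
    with :func:`read_gmt`)."""
    lines = []
    for term in collection.terms:
        lines.append("\t".join([term.term_id, term.name, *sorted(term.members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def _check_margins(k: int, n: int, K: int, N: int) -> None:
    for label, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise InvalidCountError(f"{label}={v!r} must be a non-negative integer")
    if n > N or K > N:
        raise InvalidCountError(f"margins exceed universe: n={n}, K={K}, N={N}")
    if k > min(n, K):
        raise InvalidCountError(f"overlap k={k} exceeds min(n={n}, K={K})")


def hypergeometric_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``X`` counts term genes in a sample of ``n`` drawn without replacement
    from a universe of ``N`` genes containing ``K`` term genes. Stable for
    universes up to ~1e5 (computed via scipy's survival function in log
    space).
    """
    _check_margins(k, n, K, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_pvalue(k: int, n: int, K: int, N: int) -> float:
    """EASE-style conservative tail: the overlap is reduced by one before
    taking the upper tail on the same margins (so a single-gene overlap is
    never significant). Requires ``k >= 1``."""
    _check_margins(k, n, K, N)
    if k < 1:
        raise InvalidCountError("ease_pvalue requires overlap k >= 1")
    return hypergeometric_pvalue(max(k - 1, 0), n, K, N)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    For sorted p-values p_(1) <= ... <= p_(m), the adjusted value is
    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InvalidCountError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation statistics for one tested gene set."""

    term_id: str
    term_name: str
    overlap_genes: frozenset[str]
    k: int
    n: int
    K: int
    N: int
    p: float
    p_bh: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise InvalidCountError(f"{self.term_id}: invalid overlap k={self.k}")
        if not (0 < self.p <= 1) or not (self.p <= self.p_bh + 1e-15) or self.p_bh > 1 + 1e-15:
            raise InvalidCountError(
                f"{self.term_id}: invalid p/p_bh pair ({self.p}, {self.p_bh})"
            )


def run_enrichment(
    gene_set: GeneSet,
    collection: AnnotationCollection,
    *,
    alpha: float = 0.01,
    min_overlap: int = 2,
    method: str = "hypergeometric",
) -> list[EnrichmentResult]:
    """Test every term of the collection against a gene set.

    Terms whose overlap with the (universe-mapped) gene set is below
    ``min_overlap`` are not tested and do not enter the BH family. Results
    are sorted by (raw p ascending, term name ascending) so output files
    are deterministic.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if method not in ("hypergeometric", "ease"):
        raise ValueError(f"unknown method {method!r}")
    tail = hypergeometric_pvalue if method == "hypergeometric" else ease_pvalue

    mapped = gene_set.members & collection.universe
    unmapped = len(gene_set.members) - len(mapped)
    if not mapped:
        raise EmptyIntersectionError(
            f"no gene of {gene_set.name!r} maps into the "
            f"{collection.category} universe (N={len(collection.universe)})"
        )
    if unmapped:
        logger.info(
            "%s: %d of %d genes outside the %s universe were not tested",
            gene_set.name, unmapped, len(gene_set.members), collection.category,
        )
    n = len(mapped)
    N = len(collection.universe)

    tested: list[tuple[AnnotationTerm, frozenset[str], float]] = []
    for term in collection.terms:
        overlap = term.members & mapped
        if len(overlap) < min_overlap:
            continue
        p = tail(len(overlap), n, len(term.members), N)
        tested.append((term, overlap, p))
    if not tested:
        return []
    logger.info(
        "%s vs %s: tested %d/%d terms (min_overlap=%d, n=%d, N=%d, method=%s)",
        gene_set.name, collection.category, len(tested), len(collection.terms),
        min_overlap, n, N, method,
    )
    adjusted = bh_adjust([p for _, _, p in tested])
    results = [
        EnrichmentResult(
            term_id=term.term_id,
            term_name=term.name,
            overlap_genes=overlap,
            k=len(overlap),
            n=n,
            K=len(term.members),
            N=N,
            p=p,
            p_bh=float(q),
            significant=bool(q < alpha),
        )
        for (term, overlap, p), q in zip(tested, adjusted)
    ]
    results.sort(key=lambda r: (r.p, r.term_name))
    return results


@dataclass(frozen=True)
class ComparisonRow:
    """One term in a two-disease enrichment comparison; statistics from
    whichever table(s) the term was significant in."""

    term_id: str
    term_name: str
    p_a: float | None = None
    p_bh_a: float | None = None
    p_b: float | None = None
    p_bh_b: float | None = None


@dataclass(frozen=True)
class PathwayComparison:
    """Partition of the union of two diseases' significant terms."""

    shared_terms: tuple[ComparisonRow, ...]
    a_specific_terms: tuple[ComparisonRow, ...]
    b_specific_terms: tuple[ComparisonRow, ...]

    @property
    def n_shared(self) -> int:
        return len(self.shared_terms)

    @property
    def n_a_specific(self) -> int:
        return len(self.a_specific_terms)

    @property
    def n_b_specific(self) -> int:
        return len(self.b_specific_terms)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for status, group in (
            ("shared", self.shared_terms),
            ("a_specific", self.a_specific_terms),
            ("b_specific", self.b_specific_terms),
        ):
            for r in group:
                rows.append(
                    {
                        "term_id": r.term_id,
                        "term_name": r.term_name,
                        "status": status,
                        "p_a": r.p_a,
                        "p_bh_a": r.p_bh_a,
                        "p_b": r.p_b,
                        "p_bh_b": r.p_bh_b,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["term_id", "term_name", "status", "p_a", "p_bh_a", "p_b", "p_bh_b"],
        )


def compare_enrichments(table_a, table_b) -> PathwayComparison:
    """Partition significant terms of two enrichment tables (same
    collection) into shared / A-specific / B-specific.

    Accepts any records exposing ``term_id``, ``term_name``, ``p``,
    ``p_bh`` and ``significant`` (e.g. :class:`EnrichmentResult` lists or
    curated published tables).
    """
    sig_a = {r.term_id: r for r in table_a if r.significant}
    sig_b = {r.term_id: r for r in table_b if r.significant}
    shared_ids = sorted(sig_a.keys() & sig_b.keys())
    a_ids = sorted(sig_a.keys() - sig_b.keys())
    b_ids = sorted(sig_b.keys() - sig_a.keys())
    shared = tuple(
        ComparisonRow(
            term_id=i,
            term_name=sig_a[i].term_name,
            p_a=sig_a[i].p,
            p_bh_a=sig_a[i].p_bh,
            p_b=sig_b[i].p,
            p_bh_b=sig_b[i].p_bh,
        )
        for i in shared_ids
    )
    only_a = tuple(
        ComparisonRow(term_id=i, term_name=sig_a[i].term_name, p_a=sig_a[i].p, p_bh_a=sig_a[i].p_bh)
        for i in a_ids
    )
    only_b = tuple(
        ComparisonRow(term_id=i, term_name=sig_b[i].term_name, p_b=sig_b[i].p, p_bh_b=sig_b[i].p_bh)
        for i in b_ids
    )
    return PathwayComparison(shared_terms=shared, a_specific_terms=only_a, b_specific_terms=only_b)


@dataclass(frozen=True)
class TermGeneBreakdown:
    """Partition of one term's member genes by disease-set membership."""

    term_id: str
    a_only_members: frozenset[str]
    b_only_members: frozenset[str]
    both_members: frozenset[str]
    unassigned_members: frozenset[str]


def pathway_gene_breakdown(
    term_id: str,
    collection: AnnotationCollection,
    set_a: GeneSet,
    set_b: GeneSet,
) -> TermGeneBreakdown:
    """Split a term's member genes into A-only / B-only / both / neither."""
    term = collection[term_id]
    both = term.members & set_a.members & set_b.members
    a_only = (term.members & set_a.members) - both
    b_only = (term.members & set_b.members) - both
    unassigned = term.members - set_a.members - set_b.members
    return TermGeneBreakdown(
        term_id=term_id,
        a_only_members=frozenset(a_only),
        b_only_members=frozenset(b_only),
        both_members=frozenset(both),
        unassigned_members=frozenset(unassigned),
    )


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "genes": ",".join(sorted(r.overlap_genes)),
            "p": PVALUE_FORMAT.format(r.p),
            "p_bh": PVALUE_FORMAT.format(r.p_bh),
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k", "K", "n", "N", "genes", "p", "p_bh", "significant"],
    )


def write_results(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> list[EnrichmentResult]:
    """Read an enrichment TSV written by :func:`write_results`."""
    frame = pd.read_csv(path, sep="\t", dtype={"genes": str})
    out = []
    for _, row in frame.iterrows():
        genes = row["genes"]
        members = frozenset(str(genes).split(",")) if isinstance(genes, str) and genes else frozenset()
        out.append(
            EnrichmentResult(
                term_id=str(row["term_id"]),
                term_name=str(row["term_name"]),
                overlap_genes=members,
                k=int(row["k"]),
                n=int(row["n"]),
                K=int(row["K"]),
                N=int(row["N"]),
                p=float(row["p"]),
                p_bh=float(row["p_bh"]),
                significant=bool(row["significant"]),
            )
        )
    return out


def write_comparison(comparison: PathwayComparison, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write a two-disease comparison as TSV and (optionally) a JSON summary."""
    comparison.to_frame().to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        summary = {
            "n_shared": comparison.n_shared,
            "n_a_specific": comparison.n_a_specific,
            "n_b_specific": comparison.n_b_specific,
            "shared": [r.term_name for r in comparison.shared_terms],
            "a_specific": [r.term_name for r in comparison.a_specific_terms],
            "b_specific": [r.term_name for r in comparison.b_specific_terms],
        }
        Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")
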