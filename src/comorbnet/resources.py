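"""Bundled reference tables.

The package ships the previously reported KEGG pathway enrichment tables
for the nicotine-addiction and schizophrenia candidate-gene sets (pathway
name, raw hypergeometric p, BH-adjusted p, contributing genes; every row
passed the P_BH < 0.01 gate of the original analysis). These tables were
produced against 2017-era KEGG/interactome snapshots and are used as
curated *inputs* — for the name-level comparison of the two diseases'
significant pathways and for term-gene breakdowns — never as values this
package claims to recompute.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as importlib_resources

import pandas as pd

__all__ = ["ReportedEnrichmentRow", "load_reported_pathway_table", "reported_pathway_gene_sets"]

_FILES = {
    "nicotine": "kegg_enrichment_nicotine.tsv",
    "schizophrenia": "kegg_enrichment_schizophrenia.tsv",
}


@dataclass(frozen=True)
class ReportedEnrichmentRow:
    """A published enrichment-table row; duck-compatible with
    :func:`comorbnet.enrichment.compare_enrichments` (pathway names double
    as term ids)."""

    term_id: str
    term_name: str
    p: float
    p_bh: float
    genes: frozenset[str]
    significant: bool = True


def load_reported_pathway_table(disease: str) -> list[ReportedEnrichmentRow]:
    """Load the bundled pathway enrichment table for ``'nicotine'`` or
    ``'schizophrenia'``."""
    try:
        fname = _FILES[disease]
    except KeyError:
        raise ValueError(f"unknown disease {disease!r}; expected one of {sorted(_FILES)}") from None
    with importlib_resources.files("comorbnet.data").joinpath(fname).open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    return [
        ReportedEnrichmentRow(
            term_id=row["pathway"],
            term_name=row["pathway"],
            p=float(row["p"]),
            p_bh=float(row["p_bh"]),
            genes=frozenset(str(row["genes"]).split(",")),
        )
        for _, row in frame.iterrows()
    ]


def reported_pathway_gene_sets(disease: str) -> dict[str, frozenset[str]]:
    """Pathway name -> contributing genes, from the bundled table."""
    return {row.term_name: row.genes for row in load_reported_pathway_table(disease)}
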