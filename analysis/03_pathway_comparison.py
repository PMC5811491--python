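#!/usr/bin/env python
"""Compare the two diseases' published significant KEGG pathway tables.

The package ships the reported enrichment tables for the
nicotine-addiction (20 pathways) and schizophrenia (331-gene set, 23
pathways) analyses. Comparing them by pathway name partitions the union
into 12 shared pathways (synapse/signalling plus the five drug-addiction
pathways), 8 nicotine-specific and 11 schizophrenia-specific ones.
"""

import argparse
from pathlib import Path

from comorbnet.enrichment import compare_enrichments, write_comparison
from comorbnet.resources import load_reported_pathway_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results/pathway_comparison"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    na = load_reported_pathway_table("nicotine")
    scz = load_reported_pathway_table("schizophrenia")
    comparison = compare_enrichments(na, scz)
    write_comparison(comparison, args.outdir / "comparison.tsv",
                     args.outdir / "comparison.json")

    print(f"nicotine addiction: {len(na)} significant pathways; "
          f"schizophrenia: {len(scz)}")
    print(f"shared: {comparison.n_shared}; nicotine-specific: "
          f"{comparison.n_a_specific}; schizophrenia-specific: {comparison.n_b_specific}")
    print("shared pathways:")
    for row in comparison.shared_terms:
        print(f"  {row.term_name}  (P_BH {row.p_bh_a:.2e} / {row.p_bh_b:.2e})")
    print(f"wrote {args.outdir / 'comparison.tsv'}")


if __name__ == "__main__":
    main()
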