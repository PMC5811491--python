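#!/usr/bin/env python
"""Partition the two disease gene sets into A-only / shared / B-only.

At the study configuration (276- and 331-gene sets) the intersection is
52 genes; those shared genes are the anchor of both the shared-pathway
comparison and the network candidate prediction downstream.
"""

import argparse
from pathlib import Path

from comorbnet.catalog import compare_sets, load_gene_list, write_overlap_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--genes-a", type=Path,
                        default=Path("results/synthetic/disease_a.genes.txt"))
    parser.add_argument("--genes-b", type=Path,
                        default=Path("results/synthetic/disease_b.genes.txt"))
    parser.add_argument("--outdir", type=Path, default=Path("results/overlap"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    set_a = load_gene_list(args.genes_a)
    set_b = load_gene_list(args.genes_b)
    report = compare_sets(set_a, set_b)
    out = args.outdir / "gene_overlap.tsv"
    write_overlap_report(report, out)

    print(f"{set_a.name}: {report.n_a} genes; {set_b.name}: {report.n_b} genes")
    print(f"shared: {report.n_shared}; {set_a.name}-only: {len(report.a_only)}; "
          f"{set_b.name}-only: {len(report.b_only)}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
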