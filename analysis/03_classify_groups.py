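#!/usr/bin/env python
"""Classify the OGCs into the nine phyletic groups and tabulate the results.

Writes the per-group OGC/protein table, the 7-region Venn counts over the
three major lineages, and the per-species OGC occupancy matrix.
"""

import argparse
from pathlib import Path

from ogclust import SpeciesTaxonomy, species_occupancy, tabulate_groups, venn_counts
from ogclust.mcl import read_groups
from ogclust.phyletic import write_occupancy_tsv
from ogclust.synthetic import GroundTruth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="results/cohort")
    parser.add_argument("--outdir", default="results")
    args = parser.parse_args()
    cohort, outdir = Path(args.cohort), Path(args.outdir)

    taxonomy = SpeciesTaxonomy.from_tsv(cohort / "species.tsv")
    truth = GroundTruth.from_json(cohort / "truth.json")
    ogcs = read_groups(cohort / "groups.txt", truth.protein_species)

    table, _ = tabulate_groups(ogcs, taxonomy)
    table.to_tsv(outdir / "group_table.tsv")
    regions = venn_counts(table)
    (outdir / "venn.tsv").write_text(
        "\n".join(f"{k}\t{v}" for k, v in regions.items()) + "\n"
    )
    write_occupancy_tsv(species_occupancy(ogcs, taxonomy), outdir / "occupancy.tsv")

    print(f"{table.total_ogcs} OGCs ({table.total_proteins} proteins) classified:")
    for group, row in table.rows.items():
        if row.ogc_count:
            print(f"  {group:<12} {row.ogc_count:>4} OGCs  {row.protein_count:>5} proteins")
    print(f"Venn charophyte-only region: {regions['Cha']} OGCs")


if __name__ == "__main__":
    main()
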