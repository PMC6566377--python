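#!/usr/bin/env python
"""Transfer GO terms from best reference hits and report annotation rates.

Applies the best-hit transfer rule (E < 1e-10, all ties at the minimum
E-value among GO-bearing references) and writes per-group annotation
percentages.
"""

import argparse
from pathlib import Path

from ogclust import SpeciesTaxonomy, classify_ogc, parse_hit_table, transfer_annotations
from ogclust.annotate import annotation_rates, write_annotations, write_rates
from ogclust.mcl import read_groups
from ogclust.ontology import parse_go_map
from ogclust.phyletic import GROUP_LABELS
from ogclust.synthetic import GroundTruth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="results/cohort")
    parser.add_argument("--outdir", default="results")
    args = parser.parse_args()
    cohort, outdir = Path(args.cohort), Path(args.outdir)

    taxonomy = SpeciesTaxonomy.from_tsv(cohort / "species.tsv")
    truth = GroundTruth.from_json(cohort / "truth.json")
    ref_map = parse_go_map(cohort / "refmap.tsv")
    hits = list(parse_hit_table(cohort / "gohits.tsv"))

    annotation = transfer_annotations(hits, ref_map)
    write_annotations(annotation, outdir / "annotations.tsv")

    ogcs = read_groups(cohort / "groups.txt", truth.protein_species)
    by_group = {g: [] for g in GROUP_LABELS}
    for ogc in ogcs:
        by_group[classify_ogc(ogc.species_set, taxonomy)].extend(sorted(ogc.members))
    rates = annotation_rates(annotation, by_group)
    write_rates(rates, outdir / "annotation_rates.tsv")

    print(f"annotated {len(annotation)} of {len(truth.protein_family)} proteins")
    for row in rates:
        if row.total_count:
            print(f"  {row.group:<12} {row.annotated_count:>5}/{row.total_count:<5} = {row.percent:6.2f}%")


if __name__ == "__main__":
    main()
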