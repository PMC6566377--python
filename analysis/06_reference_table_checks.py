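#!/usr/bin/env python
"""Recompute the derived numbers of the study's printed tables.

From the stored per-group reference counts, recompute totals, the Venn
regions over the three major lineages, and the annotation percentages, and
write them to results/reference_checks.tsv.
"""

import argparse
from pathlib import Path

from ogclust import OGCTable, percent_half_up, venn_counts
from ogclust.published import (
    ASSEMBLY_ANNOTATION_COUNTS,
    GO_ANNOTATED_COUNTS,
    OGC_GROUP_COUNTS,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="results")
    args = parser.parse_args()

    lines = ["quantity\tvalue"]
    table = OGCTable.from_counts(OGC_GROUP_COUNTS)
    lines.append(f"total_clustered_proteins\t{table.total_proteins}")
    lines.append(f"total_ogcs\t{table.total_ogcs}")
    print(f"totals: {table.total_proteins} proteins in {table.total_ogcs} OGCs")

    regions = venn_counts(table)
    for region, count in regions.items():
        lines.append(f"venn_{region}\t{count}")
    print(f"Venn charophyte-only region: {regions['Cha']} "
          f"(= Cha {OGC_GROUP_COUNTS['Cha'][1]} + ZCC {OGC_GROUP_COUNTS['ZCC'][1]}"
          f" + KCM {OGC_GROUP_COUNTS['KCM'][1]})")

    print("per-group GO annotation percentages:")
    for group, annotated in GO_ANNOTATED_COUNTS.items():
        pct = percent_half_up(annotated, OGC_GROUP_COUNTS[group][0])
        lines.append(f"go_annotation_pct_{group}\t{pct:.2f}")
        print(f"  {group:<12} {pct:6.2f}%")

    for label, (count, denom) in ASSEMBLY_ANNOTATION_COUNTS.items():
        lines.append(f"assembly_pct_{label}\t{percent_half_up(count, denom):.2f}")

    out = Path(args.outdir) / "reference_checks.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
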