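"""Best-hit GO term transfer and per-group annotation rates.

Each query protein inherits the GO terms of its best reference hits: among
hits with E-value strictly below the cutoff whose reference carries at least
one GO term, all hits tied at the minimum E-value contribute, and the query
receives the union of their term sets. Queries with no qualifying hit stay
unannotated and are excluded from downstream enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Set, Tuple


@dataclass
class GOAnnotationMap:
    """protein -> transferred GO terms, with the contributing references."""

    terms: Dict[str, Set[str]]
    provenance: Dict[str, Set[str]]

    def __contains__(self, protein: str) -> bool:
        return protein in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def transfer_annotations(
    query_hits, reference_go_map: Mapping[str, Set[str]], max_evalue: float = 1e-10
) -> GOAnnotationMap:
    """Transfer GO terms from best reference hits to query proteins.

    ``query_hits`` is an iterable of similarity hits (query -> reference);
    only query_id, subject_id and evalue are consumed. Hit order does not
    affect the result.
    """
    candidates: Dict[str, List[Tuple[float, str]]] = {}
    for h in query_hits:
        ref_terms = reference_go_map.get(h.subject_id)
        if h.evalue < max_evalue and ref_terms:
            candidates.setdefault(h.query_id, []).append((h.evalue, h.subject_id))

    terms: Dict[str, Set[str]] = {}
    provenance: Dict[str, Set[str]] = {}
    for query, hits in candidates.items():
        best_e = min(e for e, _ in hits)
        refs = {r for e, r in hits if e == best_e}
        terms[query] = set().union(*(reference_go_map[r] for r in refs))
        provenance[query] = refs
    return GOAnnotationMap(terms=terms, provenance=provenance)


def percent_half_up(numerator: int, denominator: int) -> float:
    """100*numerator/denominator, half-up rounded to 2 decimals."""
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class AnnotationRateRow:
    group: str
    annotated_count: int
    total_count: int
    percent: float
    undefined: bool = False


def annotation_rates(
    annotation_map: GOAnnotationMap,
    proteins_by_group: Mapping[str, Iterable[str]],
) -> List[AnnotationRateRow]:
    """Per phyletic group: how many member proteins carry transferred GO terms.

    A group with zero proteins gets percent 0.0 with the ``undefined`` flag.
    """
    rows = []
    for group, proteins in proteins_by_group.items():
        proteins = list(proteins)
        annotated = sum(1 for p in proteins if p in annotation_map)
        if proteins:
            rows.append(
                AnnotationRateRow(
                    group, annotated, len(proteins), percent_half_up(annotated, len(proteins))
                )
            )
        else:
            rows.append(AnnotationRateRow(group, 0, 0, 0.0, undefined=True))
    return rows


def write_annotations(ann: GOAnnotationMap, path) -> None:
    lines = [f"{p}\t" + ";".join(sorted(ann.terms[p])) for p in sorted(ann.terms)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_annotations(path) -> GOAnnotationMap:
    terms: Dict[str, Set[str]] = {}
    for line in open(path):
        line = line.rstrip("\n")
        if not line:
            continue
        protein, _, ts = line.partition("\t")
        terms[protein] = {t for t in ts.split(";") if t}
    return GOAnnotationMap(terms=terms, provenance={p: set() for p in terms})


def write_rates(rows: Iterable[AnnotationRateRow], path) -> None:
    lines = ["group\tannotated\ttotal\tpercent"]
    for r in rows:
        pct = "NA" if r.undefined else f"{r.percent:.2f}"
        lines.append(f"{r.group}\t{r.annotated_count}\t{r.total_count}\t{pct}")
    Path(path).write_text("\n".join(lines) + "\n")
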