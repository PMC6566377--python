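"""Parsing and threshold filtering of tabular homology and domain hits.

Similarity hits use the 14-column BLAST tabular dialect: the 12 standard
``outfmt 6`` columns extended with query and subject lengths
(``-outfmt "6 std qlen slen"``). Domain hits use a reduced 6-column table
(``query hmm_name hmm_length hmm_from hmm_to evalue``).

Both filters apply strict inequalities: a hit at exactly the E-value cutoff
or exactly the coverage cutoff is removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List

from .errors import HitTableError

HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore qlen slen"
).split()


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    slen: int


@dataclass(frozen=True)
class DomainHit:
    query_id: str
    hmm_name: str
    hmm_length: int
    hmm_from: int
    hmm_to: int
    evalue: float


def _parse_row(parts: List[str], row: int) -> SimilarityHit:
    if len(parts) != 14:
        raise HitTableError(
            f"row {row}: expected 14 tab-separated columns, got {len(parts)}"
        )
    try:
        hit = SimilarityHit(
            query_id=parts[0],
            subject_id=parts[1],
            percent_identity=float(parts[2]),
            alignment_length=int(parts[3]),
            mismatches=int(parts[4]),
            gap_opens=int(parts[5]),
            qstart=int(parts[6]),
            qend=int(parts[7]),
            sstart=int(parts[8]),
            send=int(parts[9]),
            evalue=float(parts[10]),
            bitscore=float(parts[11]),
            qlen=int(parts[12]),
            slen=int(parts[13]),
        )
    except ValueError as exc:
        raise HitTableError(f"row {row}: {exc}") from None
    if hit.qlen <= 0:
        raise HitTableError(f"row {row}: qlen must be positive, got {hit.qlen}")
    if not (1 <= hit.qstart <= hit.qend <= hit.qlen):
        raise HitTableError(
            f"row {row}: require 1 <= qstart <= qend <= qlen, got "
            f"qstart={hit.qstart} qend={hit.qend} qlen={hit.qlen}"
        )
    if hit.evalue < 0:
        raise HitTableError(f"row {row}: negative E-value {hit.evalue}")
    return hit


def parse_hit_table(path) -> Iterator[SimilarityHit]:
    """Yield validated similarity hits; malformed rows raise with their number."""
    with open(path) as fh:
        for row, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield _parse_row(line.split("\t"), row)


def parse_domain_table(path) -> Iterator[DomainHit]:
    with open(path) as fh:
        for row, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise HitTableError(
                    f"row {row}: expected 6 tab-separated columns, got {len(parts)}"
                )
            try:
                hit = DomainHit(
                    query_id=parts[0],
                    hmm_name=parts[1],
                    hmm_length=int(parts[2]),
                    hmm_from=int(parts[3]),
                    hmm_to=int(parts[4]),
                    evalue=float(parts[5]),
                )
            except ValueError as exc:
                raise HitTableError(f"row {row}: {exc}") from None
            if not (1 <= hit.hmm_from <= hit.hmm_to <= hit.hmm_length):
                raise HitTableError(
                    f"row {row}: require 1 <= hmm_from <= hmm_to <= hmm_length"
                )
            if hit.evalue < 0:
                raise HitTableError(f"row {row}: negative E-value {hit.evalue}")
            yield hit


def query_coverage(hit: SimilarityHit) -> float:
    """Fraction of the query spanned by the alignment: (qend-qstart+1)/qlen."""
    return (hit.qend - hit.qstart + 1) / hit.qlen


def hmm_coverage(hit: DomainHit) -> float:
    return (hit.hmm_to - hit.hmm_from + 1) / hit.hmm_length


def filter_hits(
    hits: Iterable[SimilarityHit],
    max_evalue: float = 1e-5,
    min_query_cov: float = 0.5,
) -> List[SimilarityHit]:
    """Keep hits with E-value strictly below and query coverage strictly above
    the cutoffs; self-hits are dropped. Order preserved, records unmodified."""
    return [
        h
        for h in hits
        if h.query_id != h.subject_id
        and h.evalue < max_evalue
        and query_coverage(h) > min_query_cov
    ]


def filter_domain_hits(
    hits: Iterable[DomainHit],
    max_evalue: float = 1e-15,
    min_hmm_cov: float = 0.8,
) -> List[DomainHit]:
    """Keep domain hits with E-value < cutoff and HMM coverage > cutoff."""
    return [
        h for h in hits if h.evalue < max_evalue and hmm_coverage(h) > min_hmm_cov
    ]


def write_hit_table(hits: Iterable[SimilarityHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(format_hit_row(h) + "\n")


def format_hit_row(h: SimilarityHit) -> str:
    return "\t".join(
        [
            h.query_id,
            h.subject_id,
            f"{h.percent_identity:.1f}",
            str(h.alignment_length),
            str(h.mismatches),
            str(h.gap_opens),
            str(h.qstart),
            str(h.qend),
            str(h.sstart),
            str(h.send),
            format_evalue(h.evalue),
            f"{h.bitscore:.1f}",
            str(h.qlen),
            str(h.slen),
        ]
    )


def format_evalue(e: float) -> str:
    return "0.0" if e == 0 else f"{e:.3e}"
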