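"""Control-group binomial GO enrichment with multiple-testing adjustment.

For every level-6 GO term carried by proteins of a tested phyletic group, an
exact one-sample binomial test compares the group's term fraction k_T/n_T to
the control group's fraction p0 = k_C/n_C (treated as a fixed proportion,
following the analysis design). n counts GO-annotated proteins only —
unannotated proteins are excluded. P-values are adjusted per tested group
(Holm step-down by default, Benjamini-Hochberg optionally); a term is called
over-represented when the adjusted p-value is below alpha AND the observed
fraction exceeds p0.

The binomial tail is computed from scratch in log space for stability; the
two-sided variant uses the point-probability method (sum over outcomes at
most as probable as the observed one, with a small relative tolerance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .annotate import GOAnnotationMap
from .ontology import GODag


@dataclass
class TermCountTable:
    group: str
    n: int                       # GO-annotated proteins in the group
    counts: Dict[str, int] = field(default_factory=dict)  # term -> k


def count_terms(
    annotation_map: GOAnnotationMap,
    group_proteins: Iterable[str],
    dag: GODag,
    level: int = 6,
    group: str = "",
    convention: str = "shortest",
) -> TermCountTable:
    """Count, per level-``level`` term, the annotated group proteins carrying it.

    n is the number of group proteins present in the annotation map; terms
    observed in no protein are omitted.
    """
    levels = dag.levels(convention)
    n = 0
    counts: Dict[str, int] = {}
    for p in group_proteins:
        terms = annotation_map.terms.get(p)
        if terms is None:
            continue
        n += 1
        for t in terms:
            if levels.get(t) == level:
                counts[t] = counts.get(t, 0) + 1
    return TermCountTable(group=group, n=n, counts=counts)


def _log_pmf(n: int, p0: float) -> np.ndarray:
    """log C(n,j) + j log p0 + (n-j) log(1-p0) for j = 0..n."""
    j = np.arange(n + 1)
    log_comb = gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_p = np.where(j > 0, j * np.log(p0) if p0 > 0 else -np.inf, 0.0)
        term_q = np.where(n - j > 0, (n - j) * np.log1p(-p0) if p0 < 1 else -np.inf, 0.0)
    return log_comb + term_p + term_q


def binomial_test(
    k_T: int, n_T: int, p0: float, alternative: str = "greater"
) -> float:
    """Exact binomial test of k_T successes in n_T trials against proportion p0.

    ``greater``: upper-tail sum P(X >= k_T). ``two-sided``: point-probability
    method, summing P(X = j) over all j with pmf(j) <= pmf(k_T)*(1 + 1e-7).
    """
    if not (0 <= k_T <= n_T):
        raise ValueError(f"require 0 <= k_T <= n_T, got k_T={k_T}, n_T={n_T}")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"require 0 <= p0 <= 1, got {p0}")
    if n_T == 0:
        return 1.0
    logpmf = _log_pmf(n_T, p0)
    if alternative == "greater":
        tail = logpmf[k_T:]
    elif alternative == "two-sided":
        cutoff = logpmf[k_T] + math.log1p(1e-7)
        tail = logpmf[logpmf <= cutoff]
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    finite = tail[np.isfinite(tail)]
    if finite.size == 0:
        return 0.0
    return float(min(1.0, math.exp(logsumexp(finite))))


def adjust_pvalues(p_list: Sequence[float], method: str = "holm") -> List[float]:
    """Multiple-testing adjustment, returned in the input order.

    ``holm``: step-down, adj_(i) = cummax_j<=i min(1, (m-j+1) p_(j)).
    ``bh``: step-up FDR, adj_(i) = min_j>=i min(1, m p_(j) / j).
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    if method == "holm":
        stepped = np.minimum(1.0, (m - np.arange(m)) * ranked)
        adj_sorted = np.maximum.accumulate(stepped)
    elif method in ("bh", "BH", "fdr_bh"):
        stepped = np.minimum(1.0, m * ranked / np.arange(1, m + 1))
        adj_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj.tolist()


@dataclass
class EnrichmentResult:
    term_id: str
    group: str
    k_T: int
    n_T: int
    k_C: int
    n_C: int
    p0: float
    p_raw: float
    p_adj: float
    direction: str          # "over" | "under"
    significant: bool
    degenerate: bool = False  # p0 in {0, 1}: impossible/forced under the null


def enrich_group(
    tested: TermCountTable,
    control: TermCountTable,
    alpha: float = 0.05,
    method: str = "holm",
    alternative: str = "greater",
) -> List[EnrichmentResult]:
    """Test every term of the tested group against the control proportion.

    Adjustment spans all terms of this tested group (one test family per
    group). Terms absent from the control get k_C = 0 and are flagged
    degenerate rather than dropped.
    """
    if control.n == 0:
        raise ValueError("control group has no GO-annotated proteins")
    terms = sorted(tested.counts)
    raw: List[float] = []
    rows: List[EnrichmentResult] = []
    for t in terms:
        k_T = tested.counts[t]
        k_C = control.counts.get(t, 0)
        p0 = k_C / control.n
        p_raw = binomial_test(k_T, tested.n, p0, alternative)
        raw.append(p_raw)
        direction = "over" if (tested.n > 0 and k_T / tested.n > p0) else "under"
        rows.append(
            EnrichmentResult(
                term_id=t,
                group=tested.group,
                k_T=k_T,
                n_T=tested.n,
                k_C=k_C,
                n_C=control.n,
                p0=p0,
                p_raw=p_raw,
                p_adj=math.nan,
                direction=direction,
                significant=False,
                degenerate=p0 in (0.0, 1.0),
            )
        )
    for row, p_adj in zip(rows, adjust_pvalues(raw, method)):
        row.p_adj = p_adj
        row.significant = (p_adj < alpha) and row.direction == "over"
    return rows


@dataclass
class EnrichmentReport:
    rows: List[EnrichmentResult]

    def minus_log10_padj(self) -> List[float]:
        return [
            math.inf if r.p_adj == 0 else -math.log10(r.p_adj) for r in self.rows
        ]


def top_report(results: Iterable[EnrichmentResult], top_n: int = 20) -> EnrichmentReport:
    """Significant results sorted by ascending adjusted p (ties: descending
    group fraction, then term id), truncated to ``top_n``."""
    sig = [r for r in results if r.significant]
    sig.sort(key=lambda r: (r.p_adj, -(r.k_T / r.n_T if r.n_T else 0.0), r.term_id))
    return EnrichmentReport(rows=sig[:top_n])


def write_enrichment(
    results: Iterable[EnrichmentResult], path, dag: Optional[GODag] = None
) -> None:
    header = (
        "group\tterm_id\tterm_name\tnamespace\tk_T\tn_T\tk_C\tn_C\t"
        "p0\tp_raw\tp_adj\tdirection\tsignificant\tdegenerate"
    )
    lines = [header]
    for r in results:
        name = dag.name(r.term_id) if dag else ""
        ns = dag.namespace(r.term_id) if dag else ""
        lines.append(
            f"{r.group}\t{r.term_id}\t{name}\t{ns}\t{r.k_T}\t{r.n_T}\t"
            f"{r.k_C}\t{r.n_C}\t{r.p0:.6g}\t{r.p_raw:.6g}\t{r.p_adj:.6g}\t"
            f"{r.direction}\t{int(r.significant)}\t{int(r.degenerate)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
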