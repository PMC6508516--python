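"""GO-term over/under-representation of a candidate set against a
background set via the two-sided Fisher's exact test.

For each GO term annotated to at least one background transcript, the
2x2 table is

    a = candidates carrying the term       b = candidates without it
    c = non-candidate background with it   d = non-candidate background without it

so a+b is the candidate-set size and a+b+c+d the background size.
Transcript-term incidence is binary (duplicate annotations collapse).
The two-sided p-value sums the probabilities of all tables with the same
margins whose point probability does not exceed the observed table's.
Benjamini–Hochberg q-values are computed across all tested terms; no
GO-DAG ancestor propagation is applied (annotations are tested exactly
as supplied).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .seqio import AnnotationRecord

__all__ = ["EnrichmentResult", "fisher_exact_two_sided", "enrich"]


@dataclass(frozen=True)
class EnrichmentResult:
    go_id: str
    category: str
    a: int
    b: int
    c: int
    d: int
    direction: str  # "over" | "under" | "none"
    p_value: float
    fdr_q: float

    def to_row(self) -> str:
        return "\t".join([
            self.go_id, self.category,
            str(self.a), str(self.b), str(self.c), str(self.d),
            self.direction, f"{self.p_value:.6g}", f"{self.fdr_q:.6g}",
        ])


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]]."""
    for cell in (a, b, c, d):
        if cell < 0:
            raise ValueError("2x2 table cells must be non-negative")
    if (a + b + c + d) == 0:
        raise ValueError("2x2 table is empty")
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return min(float(p), 1.0)


def _direction(a: int, b: int, c: int, d: int) -> str:
    cand = a / (a + b) if (a + b) else 0.0
    rest = c / (c + d) if (c + d) else 0.0
    if cand > rest:
        return "over"
    if cand < rest:
        return "under"
    return "none"


def enrich(candidate_ids: Iterable[str], background_ids: Iterable[str],
           annotations: Mapping[str, AnnotationRecord]
           ) -> list[EnrichmentResult]:
    """Test every GO term seen in the background for enrichment in the
    candidate set.

    ``candidate_ids`` must be a subset of ``background_ids``; annotations
    may cover only part of the background (unannotated transcripts count
    as term-free). Results are sorted by p-value, then GO id.
    """
    candidates = set(candidate_ids)
    background = set(background_ids)
    extra = candidates - background
    if extra:
        raise ValueError(
            f"candidate ids not in background: {sorted(extra)[:5]}"
        )
    term_members: dict[str, set[str]] = {}
    term_category: dict[str, str] = {}
    for tid, rec in annotations.items():
        if tid not in background:
            continue
        for go_id, category in rec.terms.items():
            term_members.setdefault(go_id, set()).add(tid)
            term_category[go_id] = category

    n_cand = len(candidates)
    n_rest = len(background) - n_cand
    results: list[EnrichmentResult] = []
    for go_id in sorted(term_members):
        members = term_members[go_id]
        a = len(members & candidates)
        b = n_cand - a
        c = len(members) - a
        d = n_rest - c
        p = fisher_exact_two_sided(a, b, c, d)
        results.append(
            EnrichmentResult(
                go_id=go_id,
                category=term_category[go_id],
                a=a, b=b, c=c, d=d,
                direction=_direction(a, b, c, d),
                p_value=p,
                fdr_q=1.0,  # populated below
            )
        )
    if results:
        qvals = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(
                go_id=r.go_id, category=r.category,
                a=r.a, b=r.b, c=r.c, d=r.d,
                direction=r.direction, p_value=r.p_value,
                fdr_q=float(q),
            )
            for r, q in zip(results, qvals)
        ]
    results.sort(key=lambda r: (r.p_value, r.go_id))
    return results
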