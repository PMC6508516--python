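"""The core presence/absence procedure: contamination filtering, the
five-way partition of queries by which reference databases contain a
significant homolog, intersection with rhizome-expressed reference
peptides, candidate extraction, and the filter accounting.

The partition classifies every query contig into exactly one of:

* ``both`` — significant hit in the annual and the rhizomatous reference;
* ``only_annual`` — hit in the annual reference only;
* ``only_rhiz_not_in_rhizome_assembly`` — hit in the rhizomatous
  reference only, but its subject peptide is not evidenced as expressed
  in reference rhizome tissue;
* ``only_rhiz_in_rhizome_assembly`` — hit in the rhizomatous reference
  only AND the subject peptide is also the hit of a rhizome-tissue
  assembly contig — the pool candidates are drawn from;
* ``none`` — no hit in either reference.

Candidates are the rhizome-assembly-supported pool minus lowly expressed
transcripts (FPKM below threshold) and probable contaminants (top hit
from a non-plant organism). The two removal filters commute with the
partition intersection, so filter order does not change the final set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .homology import top_hits_by_query
from .seqio import HomologyHit

__all__ = ["VennPartition", "CandidateSet", "contamination_filter",
           "venn_partition", "partition_accounting", "select_candidates"]

MATCH_MODES = ("top", "any")


@dataclass(frozen=True)
class VennPartition:
    """Disjoint, exhaustive five-way classification of the query id set."""

    both: frozenset[str]
    only_annual: frozenset[str]
    only_rhiz_not_in_rhizome_assembly: frozenset[str]
    only_rhiz_in_rhizome_assembly: frozenset[str]
    none: frozenset[str]

    def categories(self) -> dict[str, frozenset[str]]:
        return {
            "both": self.both,
            "only_annual": self.only_annual,
            "only_rhiz_not_in_rhizome_assembly": self.only_rhiz_not_in_rhizome_assembly,
            "only_rhiz_in_rhizome_assembly": self.only_rhiz_in_rhizome_assembly,
            "none": self.none,
        }

    def validate(self) -> None:
        cats = list(self.categories().values())
        total = sum(len(c) for c in cats)
        union: set[str] = set().union(*cats)
        if total != len(union):
            raise ValueError("partition categories overlap")

    @property
    def all_queries(self) -> frozenset[str]:
        return frozenset().union(*self.categories().values())

    @property
    def annual_marginal(self) -> frozenset[str]:
        return self.both | self.only_annual

    @property
    def rhizomatous_marginal(self) -> frozenset[str]:
        return (self.both | self.only_rhiz_not_in_rhizome_assembly
                | self.only_rhiz_in_rhizome_assembly)

    @property
    def only_rhizomatous(self) -> frozenset[str]:
        """Hits in the rhizomatous reference but none in the annual one,
        regardless of rhizome-assembly support."""
        return (self.only_rhiz_not_in_rhizome_assembly
                | self.only_rhiz_in_rhizome_assembly)


@dataclass(frozen=True)
class CandidateSet:
    """Surviving candidate contigs with their unique reference-peptide
    subjects and per-candidate provenance."""

    candidate_ids: frozenset[str]
    unique_subjects: frozenset[str]
    provenance: dict[str, dict] = field(default_factory=dict, compare=False)


def contamination_filter(query_ids: Iterable[str],
                         nr_style_hits: Sequence[HomologyHit],
                         plant_taxa: Iterable[str],
                         subject_taxa: Mapping[str, str]
                         ) -> tuple[set[str], set[str]]:
    """Partition queries into (kept, removed) by top-hit organism.

    A query is removed iff it has at least one hit and the organism of its
    top hit is not in the plant whitelist; queries with no hits are kept —
    absence of annotation is not evidence of contamination.

    ``subject_taxa`` maps subject ids in the hit table to organism labels.
    """
    plant = set(plant_taxa)
    if not plant:
        raise ValueError("plant taxon whitelist must not be empty")
    query_ids = set(query_ids)
    tops = top_hits_by_query(h for h in nr_style_hits if h.query_id in query_ids)
    kept: set[str] = set()
    removed: set[str] = set()
    for qid in query_ids:
        hit = tops.get(qid)
        if hit is None:
            kept.add(qid)
            continue
        taxon = subject_taxa.get(hit.subject_id, "")
        (removed if taxon not in plant else kept).add(qid)
    return kept, removed


def venn_partition(query_ids: Iterable[str],
                   hits_vs_annual: Sequence[HomologyHit],
                   hits_vs_rhizomatous: Sequence[HomologyHit],
                   rhizome_expressed_subjects: Iterable[str],
                   match_mode: str = "top") -> VennPartition:
    """Assign every query to exactly one of the five presence/absence
    categories.

    ``rhizome_expressed_subjects`` is the set of rhizomatous-reference
    peptide ids evidenced as expressed in rhizome tissue (top hits of the
    rhizome-assembly contigs). ``match_mode`` controls the subcategory
    test for only-rhizomatous queries: ``"top"`` requires the query's top
    rhizomatous subject to be rhizome-expressed; ``"any"`` accepts any of
    its rhizomatous subjects.
    """
    if match_mode not in MATCH_MODES:
        raise ValueError(f"match_mode must be one of {MATCH_MODES}")
    queries = set(query_ids)
    for hits, label in ((hits_vs_annual, "annual"), (hits_vs_rhizomatous, "rhizomatous")):
        unknown = {h.query_id for h in hits} - queries
        if unknown:
            raise ValueError(
                f"{label} hit table references unknown query ids: "
                f"{sorted(unknown)[:5]}"
            )
    annual_hit = {h.query_id for h in hits_vs_annual}
    rhiz_by_query: dict[str, list[HomologyHit]] = {}
    for h in hits_vs_rhizomatous:
        rhiz_by_query.setdefault(h.query_id, []).append(h)
    rhiz_tops = top_hits_by_query(hits_vs_rhizomatous)
    expressed = set(rhizome_expressed_subjects)

    both: set[str] = set()
    only_annual: set[str] = set()
    only_rhiz_out: set[str] = set()
    only_rhiz_in: set[str] = set()
    none: set[str] = set()
    for qid in queries:
        in_annual = qid in annual_hit
        in_rhiz = qid in rhiz_by_query
        if in_annual and in_rhiz:
            both.add(qid)
        elif in_annual:
            only_annual.add(qid)
        elif in_rhiz:
            if match_mode == "top":
                supported = rhiz_tops[qid].subject_id in expressed
            else:
                supported = any(h.subject_id in expressed for h in rhiz_by_query[qid])
            (only_rhiz_in if supported else only_rhiz_out).add(qid)
        else:
            none.add(qid)
    part = VennPartition(
        both=frozenset(both),
        only_annual=frozenset(only_annual),
        only_rhiz_not_in_rhizome_assembly=frozenset(only_rhiz_out),
        only_rhiz_in_rhizome_assembly=frozenset(only_rhiz_in),
        none=frozenset(none),
    )
    part.validate()
    return part


_CATEGORY_KEYS = ("both", "only_annual", "only_rhiz_not_in_rhizome_assembly",
                  "only_rhiz_in_rhizome_assembly", "none")


def partition_accounting(partition: "VennPartition | Mapping[str, int]"
                         ) -> dict[str, int]:
    """Totals and marginals implied by the five category counts.

    Accepts either a :class:`VennPartition` (validated for disjointness) or
    a mapping of the five category names to counts, and returns the full
    accounting: each category, the two per-reference marginals, the
    only-rhizomatous total, and the grand total.
    """
    if isinstance(partition, VennPartition):
        partition.validate()
        counts = {k: len(v) for k, v in partition.categories().items()}
    else:
        counts = {k: int(partition[k]) for k in _CATEGORY_KEYS}
        if any(v < 0 for v in counts.values()):
            raise ValueError("category counts must be non-negative")
    report = dict(counts)
    report["only_rhizomatous"] = (
        counts["only_rhiz_not_in_rhizome_assembly"]
        + counts["only_rhiz_in_rhizome_assembly"]
    )
    report["with_annual_hit"] = counts["both"] + counts["only_annual"]
    report["with_rhizomatous_hit"] = counts["both"] + report["only_rhizomatous"]
    report["total"] = sum(counts[k] for k in _CATEGORY_KEYS)
    return report


def select_candidates(partition: VennPartition,
                      fpkm_by_id: Mapping[str, float],
                      contamination_kept: Iterable[str],
                      min_fpkm: float = 1.0,
                      rhiz_top_subject: Mapping[str, str] | None = None,
                      top_hit_taxon: Mapping[str, str] | None = None
                      ) -> CandidateSet:
    """Extract final candidates from the rhizome-assembly-supported pool.

    candidates = only_rhiz_in_rhizome_assembly
                 AND fpkm >= min_fpkm
                 AND not flagged as contamination

    ``rhiz_top_subject`` maps query id to its top rhizomatous-reference
    subject; the distinct subjects of the candidates form
    ``unique_subjects``. Missing FPKM is treated as 0 (never quantified).
    """
    kept = set(contamination_kept)
    rhiz_top_subject = rhiz_top_subject or {}
    top_hit_taxon = top_hit_taxon or {}
    candidates = {
        qid for qid in partition.only_rhiz_in_rhizome_assembly
        if fpkm_by_id.get(qid, 0.0) >= min_fpkm and qid in kept
    }
    subjects = {rhiz_top_subject[q] for q in candidates if q in rhiz_top_subject}
    provenance = {
        q: {
            "fpkm": fpkm_by_id.get(q, 0.0),
            "top_hit_taxon": top_hit_taxon.get(q, ""),
            "rhizomatous_subject": rhiz_top_subject.get(q, ""),
        }
        for q in sorted(candidates)
    }
    return CandidateSet(
        candidate_ids=frozenset(candidates),
        unique_subjects=frozenset(subjects),
        provenance=provenance,
    )
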