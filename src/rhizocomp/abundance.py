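"""FPKM computation, low-expression filtering, and a naive exact-substring
fragment counter for synthetic reads.

FPKM (fragments per kilobase of transcript per million mapped fragments)
is computed from estimated counts and effective lengths exactly as a
quantifier reports them:

    fpkm_i = est_count_i * 1e9 / (eff_length_i * N),   N = sum_j est_count_j

The per-million denominator N is the summed estimated count over the run,
matching standard practice for quantifier output. The expression filter
removes transcripts with FPKM strictly below the threshold: an FPKM of
exactly 1.0 survives a threshold of 1.0.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .orfscan import reverse_complement
from .seqio import AbundanceRecord, TranscriptRecord

__all__ = ["compute_fpkm", "expression_filter", "count_fragments",
           "effective_length", "records_from_counts"]


def compute_fpkm(records: Sequence[AbundanceRecord]) -> list[AbundanceRecord]:
    """Populate ``fpkm`` on every record in place (and return the list).

    Raises ``ValueError`` when the summed estimated count is zero — FPKM is
    undefined without any mapped fragment.
    """
    total = sum(rec.est_count for rec in records)
    if total <= 0:
        raise ValueError("FPKM undefined: total estimated count is zero")
    for rec in records:
        rec.fpkm = rec.est_count * 1e9 / (rec.eff_length_nt * total)
    return list(records)


def expression_filter(records: Iterable[AbundanceRecord],
                      threshold: float = 1.0) -> tuple[set[str], set[str]]:
    """Partition transcript ids into (kept, removed) by FPKM.

    Removal is strict: a transcript is removed iff fpkm < threshold, so a
    value exactly at the threshold is kept.
    """
    kept: set[str] = set()
    removed: set[str] = set()
    for rec in records:
        if rec.fpkm is None:
            raise ValueError(
                f"transcript {rec.transcript_id!r}: fpkm not populated; "
                "run compute_fpkm first"
            )
        (removed if rec.fpkm < threshold else kept).add(rec.transcript_id)
    return kept, removed


def effective_length(length_nt: int, fragment_length: int) -> float:
    """Number of distinct fragment start positions, floored at 1."""
    return float(max(length_nt - fragment_length + 1, 1))


def count_fragments(reads: Sequence[str],
                    transcripts: Sequence[TranscriptRecord]) -> dict[str, float]:
    """Assign reads to transcripts by exact substring match (either strand).

    A read matching a single transcript contributes 1 to its count; a read
    matching k transcripts contributes 1/k to each; unmatched reads
    contribute nothing. Matching is positional-agnostic: a read occurring
    at several positions of one transcript still counts once for it.

    Implemented with a window index per distinct read length, so the cost
    is linear in total transcript length per length class.
    """
    counts: dict[str, float] = {t.id: 0.0 for t in transcripts}
    if not reads:
        return counts
    by_length: dict[int, list[str]] = {}
    for read in reads:
        by_length.setdefault(len(read), []).append(read.upper())
    for rlen, group in by_length.items():
        index: dict[str, set[str]] = {}
        for t in transcripts:
            seq = t.seq
            for strand_seq in (seq, reverse_complement(seq)):
                for i in range(len(strand_seq) - rlen + 1):
                    index.setdefault(strand_seq[i:i + rlen], set()).add(t.id)
        for read in group:
            owners = index.get(read)
            if not owners:
                continue
            share = 1.0 / len(owners)
            for tid in owners:
                counts[tid] += share
    return counts


def records_from_counts(counts: Mapping[str, float],
                        transcripts: Sequence[TranscriptRecord],
                        fragment_length: int) -> list[AbundanceRecord]:
    """Build abundance records from a fragment-count map, with effective
    length derived from transcript length and the fragment length."""
    records = []
    for t in transcripts:
        records.append(
            AbundanceRecord(
                transcript_id=t.id,
                eff_length_nt=effective_length(t.length_nt, fragment_length),
                est_count=float(counts.get(t.id, 0.0)),
                length_nt=t.length_nt,
            )
        )
    return records
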