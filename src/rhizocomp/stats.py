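"""Assembly-level descriptive statistics: contig counts, length summary,
N50 and GC content.

N50 is the largest contig length L such that contigs of length >= L make
up at least half of the total assembly length. The comparison uses exact
integer arithmetic (2 * coverage >= total), so results are bit-exact on
integer inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["AssemblyStats", "n50", "gc_content", "summarize"]


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_nt: int
    mean_len: float
    median_len: float
    n50: int
    min_len: int
    max_len: int
    gc_fraction: float

    def report_rows(self) -> list[tuple[str, str]]:
        """Key-value rows for the assembly report."""
        return [
            ("Total number of sequences", f"{self.n_contigs:,}"),
            ("Total length (bp)", f"{self.total_nt:,}"),
            ("Mean length of sequences (bp)", f"{self.mean_len:,.0f}"),
            ("Median length of sequences (bp)", f"{self.median_len:,.0f}"),
            ("N50 value of sequences (bp)", f"{self.n50:,}"),
            ("Range of sequence length (bp)", f"{self.min_len:,}-{self.max_len:,}"),
            ("GC content", f"{100.0 * self.gc_fraction:.2f}%"),
        ]


def n50(lengths: Iterable[int]) -> int:
    """Largest length L whose >=L contigs cover at least half the assembly.

    Ties resolve to the maximum qualifying length. Raises ``ValueError`` on
    empty input or non-positive lengths.
    """
    ls = sorted(int(x) for x in lengths)
    if not ls:
        raise ValueError("n50 of an empty length collection is undefined")
    if ls[0] <= 0:
        raise ValueError("contig lengths must be positive")
    total = sum(ls)
    coverage = 0
    for length in reversed(ls):
        coverage += length
        if 2 * coverage >= total:
            return length
    raise AssertionError("unreachable: full coverage always reaches half")


def gc_content(records) -> float:
    """Pooled G+C fraction over all records; N bases are excluded from the
    denominator. Raises ``ValueError`` when no unambiguous base is present."""
    gc = 0
    acgt = 0
    for rec in records:
        seq = rec.seq if hasattr(rec, "seq") else str(rec)
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous bases in input")
    return gc / acgt


def summarize(records) -> AssemblyStats:
    """Aggregate descriptive statistics over a record collection."""
    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty assembly")
    lengths = np.array([rec.length_nt for rec in records], dtype=np.int64)
    return AssemblyStats(
        n_contigs=len(records),
        total_nt=int(lengths.sum()),
        mean_len=float(lengths.mean()),
        median_len=float(np.median(lengths)),
        n50=n50(lengths.tolist()),
        min_len=int(lengths.min()),
        max_len=int(lengths.max()),
        gc_fraction=gc_content(records),
    )


def summarize_lengths(lengths: Sequence[int]) -> dict[str, float]:
    """Length-only summary used when sequences themselves are not at hand."""
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty length collection")
    return {
        "n": int(arr.size),
        "total": int(arr.sum()),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "n50": n50(arr.tolist()),
        "min": int(arr.min()),
        "max": int(arr.max()),
    }
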