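"""Translated homology search with Karlin–Altschul E-values.

Nucleotide queries are translated in six frames and aligned to every
subject peptide by Smith–Waterman local alignment (BLOSUM62, affine gaps
11/1). The search is exact: full dynamic programming over all pairs,
with an optional k-mer prefilter for larger runs. E-values follow the
closed form

    E = K * m * n * exp(-lambda * S)

with m the translated query-frame length (aa), n the summed subject
length of the database (aa), and S the raw alignment score. The defaults
lambda = 0.267, K = 0.041 are the standard gapped BLOSUM62/11,1
constants; no edge-length correction is applied.

External searches in the 12-column tabular format are drop-in
replacements for the built-in engine at real scale (see ``seqio``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .orfscan import FRAME_ORDER, translate_frames
from .seqio import HomologyHit, ProteinRecord, TranscriptRecord

__all__ = ["ScoringScheme", "LocalAlignment", "local_align", "evalue",
           "bitscore", "search", "top_hit", "top_hits_by_query"]


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and the Karlin–Altschul
    constants that convert raw scores to bit scores and E-values."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    k_: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lambda_ <= 0 or self.k_ <= 0:
            raise ValueError("lambda and K must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(str(self.matrix.alphabet))

    def make_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # a gap of length g costs gap_open + g * gap_extend (BLAST convention)
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class LocalAlignment:
    """Raw Smith–Waterman score with the aligned spans (1-based inclusive,
    amino-acid coordinates on each sequence; zeros when score is 0)."""

    score: int
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0
    identities: int = 0
    align_len: int = 0
    aligned_cols: int = 0
    gap_opens: int = 0

    @property
    def mismatches(self) -> int:
        return self.aligned_cols - self.identities


def _check_alphabet(seq: str, scheme: ScoringScheme, label: str) -> None:
    bad = set(seq) - scheme.alphabet
    if bad:
        raise ValueError(f"{label} contains characters outside the "
                         f"{scheme.matrix_name} alphabet: {sorted(bad)}")


def local_align(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME,
                spans: bool = True) -> LocalAlignment:
    """Best local alignment of two peptide strings.

    Returns score 0 (and empty spans) when either string is empty or no
    positive-scoring alignment exists. Raises ``ValueError`` on characters
    outside the substitution-matrix alphabet.
    """
    _check_alphabet(a, scheme, "first sequence")
    _check_alphabet(b, scheme, "second sequence")
    if not a or not b:
        return LocalAlignment(score=0)
    aligner = scheme.make_aligner()
    score = int(aligner.score(a, b))
    if score <= 0 or not spans:
        return LocalAlignment(score=max(score, 0))
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    a0, a1 = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b0, b1 = int(blocks_b[0][0]), int(blocks_b[-1][1])
    identities = 0
    aligned_cols = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            aligned_cols += 1
            if a[i] == b[j]:
                identities += 1
    # gapped columns = span difference between the two sequences' footprints
    gaps_a = (a1 - a0) - aligned_cols
    gaps_b = (b1 - b0) - aligned_cols
    align_len = aligned_cols + gaps_a + gaps_b
    gap_opens = max(len(blocks_a) - 1, 0)
    return LocalAlignment(
        score=score,
        a_start=a0 + 1, a_end=a1,
        b_start=b0 + 1, b_end=b1,
        identities=identities,
        align_len=align_len,
        aligned_cols=aligned_cols,
        gap_opens=gap_opens,
    )


def evalue(raw_score: float, m: int, n: int,
           scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin–Altschul expected hit count: K * m * n * exp(-lambda * S)."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions m and n must be >= 1")
    return scheme.k_ * m * n * math.exp(-scheme.lambda_ * raw_score)


def bitscore(raw_score: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Normalized score: (lambda * S - ln K) / ln 2."""
    return (scheme.lambda_ * raw_score - math.log(scheme.k_)) / math.log(2.0)


def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def _frame_to_query_coords(frame: int, aa_start: int, aa_end: int,
                           query_len_nt: int) -> tuple[int, int]:
    """Map 1-based inclusive aa coordinates in a translation frame back to
    1-based inclusive nt coordinates on the forward strand."""
    offset = abs(frame) - 1
    s = offset + 3 * (aa_start - 1) + 1
    e = offset + 3 * aa_end
    if frame > 0:
        return s, e
    return query_len_nt - e + 1, query_len_nt - s + 1


def search(queries: Sequence[TranscriptRecord], db: Sequence[ProteinRecord],
           scheme: ScoringScheme = DEFAULT_SCHEME,
           evalue_cutoff: float = 1e-20,
           seeded: bool = False, kmer_size: int = 4,
           min_shared_kmers: int = 2) -> list[HomologyHit]:
    """Six-frame translated search of nucleotide queries against a protein
    database.

    One hit is reported per (query, subject) pair — the best-scoring frame
    — when its E-value is below ``evalue_cutoff``. Output order is
    deterministic: query id, then descending bitscore, then subject id.

    ``seeded=True`` enables a k-mer prefilter (a query frame is aligned to
    a subject only when they share at least ``min_shared_kmers`` exact
    k-mers); this can only drop weak alignments and is intended for larger
    synthetic runs. The default is the exact all-pairs search.
    """
    if not db:
        raise ValueError("homology search against an empty database")
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    n_db = sum(p.length_aa for p in db)
    aligner = scheme.make_aligner()

    db_kmers = None
    if seeded:
        db_kmers = [_kmers(p.seq, kmer_size) for p in db]

    hits: list[HomologyHit] = []
    for query in queries:
        frames = translate_frames(query.seq)
        frame_kmers = None
        if seeded:
            frame_kmers = {f: _kmers(aa, kmer_size) for f, aa in frames.items()}
        for si, subject in enumerate(db):
            best_frame = 0
            best_score = 0
            for frame in FRAME_ORDER:
                aa = frames[frame]
                if not aa:
                    continue
                if seeded and len(
                    frame_kmers[frame] & db_kmers[si]
                ) < min_shared_kmers:
                    continue
                _check_alphabet(aa, scheme, f"query {query.id} frame {frame}")
                score = int(aligner.score(aa, subject.seq))
                if score > best_score:
                    best_score, best_frame = score, frame
            if best_score <= 0:
                continue
            m = len(frames[best_frame])
            ev = evalue(best_score, m, n_db, scheme)
            if ev >= evalue_cutoff:
                continue
            aln = local_align(frames[best_frame], subject.seq, scheme)
            qstart, qend = _frame_to_query_coords(
                best_frame, aln.a_start, aln.a_end, query.length_nt
            )
            pident = 100.0 * aln.identities / aln.align_len if aln.align_len else 0.0
            hits.append(
                HomologyHit(
                    query_id=query.id,
                    subject_id=subject.id,
                    pident=pident,
                    align_len=aln.align_len,
                    mismatches=aln.mismatches,
                    gap_opens=aln.gap_opens,
                    qstart=qstart,
                    qend=qend,
                    sstart=aln.b_start,
                    send=aln.b_end,
                    evalue=ev,
                    bitscore=bitscore(best_score, scheme),
                    frame=best_frame,
                    raw_score=best_score,
                )
            )
    hits.sort(key=lambda h: (h.query_id, -h.bitscore, h.subject_id))
    return hits


def top_hit(hits: Sequence[HomologyHit]) -> HomologyHit:
    """Single best hit: maximum bitscore, ties by minimum E-value, then
    lexicographically smallest subject id."""
    if not hits:
        raise ValueError("top_hit of an empty hit collection")
    return min(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))


def top_hits_by_query(hits: Iterable[HomologyHit]) -> dict[str, HomologyHit]:
    """Resolve the top hit for every query present in a hit collection."""
    grouped: dict[str, list[HomologyHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    return {q: top_hit(hs) for q, hs in grouped.items()}
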