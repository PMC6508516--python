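"""Open-reading-frame scanning: a deliberately simple coding-region
predictor for assembled transcripts.

Every maximal ATG-to-stop (or ATG-to-sequence-end) stretch of at least
``min_orf_nt`` nucleotides is reported across all six frames; within a
frame, nested ORFs sharing a stop codon collapse to the longest (the
first ATG after the previous stop). There is no coding-potential model
and no homology rescue — the rule is ORF length alone.

Coordinates are 1-based inclusive on the forward strand, as GFF readers
expect, for both forward and reverse frames. Codons containing N (or any
ambiguity) translate to ``X``; stops render as ``*``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

from .seqio import ProteinRecord, TranscriptRecord

__all__ = ["OrfCall", "FRAME_ORDER", "translate_frames", "find_orfs",
           "best_orf_per_transcript", "reverse_complement"]

FRAME_ORDER = (1, 2, 3, -1, -2, -3)

_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class OrfCall:
    """One predicted open reading frame on a transcript.

    ``cds_len_nt`` includes the stop codon when one terminates the ORF:
    3*(len(peptide)+1) if stop-terminated, else 3*len(peptide).
    """

    transcript_id: str
    frame: int
    start_nt: int
    end_nt: int
    peptide: str
    cds_len_nt: int
    stop_terminated: bool


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(seq: str, offset: int) -> str:
    aa = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        aa.append(_CODON_TABLE.get(codon, "X"))
    return "".join(aa)


def translate_frames(seq: str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six frames.

    Frames +1..+3 read the forward strand at offsets 0..2; frames -1..-3
    read the reverse complement the same way. Trailing partial codons are
    dropped.
    """
    seq = seq.upper()
    rc = reverse_complement(seq)
    out: dict[int, str] = {}
    for f in (1, 2, 3):
        out[f] = _translate(seq, f - 1)
        out[-f] = _translate(rc, f - 1)
    return out


def find_orfs(record: TranscriptRecord, min_orf_nt: int = 297) -> list[OrfCall]:
    """Report all qualifying ORFs in a transcript, all six frames.

    ``min_orf_nt`` must be >= 3 and divisible by 3. Output order is frame
    order (+1,+2,+3,-1,-2,-3) then ascending position within a frame.
    """
    if min_orf_nt < 3 or min_orf_nt % 3 != 0:
        raise ValueError("min_orf_nt must be >= 3 and divisible by 3")
    seq = record.seq
    L = len(seq)
    frames = translate_frames(seq)
    calls: list[OrfCall] = []
    for frame in FRAME_ORDER:
        aa = frames[frame]
        offset = abs(frame) - 1
        # segments between stop codons; the first M in each opens the ORF
        seg_start = 0
        n = len(aa)
        i = 0
        while i <= n:
            at_end = i == n
            if at_end or aa[i] == "*":
                m = aa.find("M", seg_start, i)
                if m != -1:
                    pep = aa[m:i]
                    stop_terminated = not at_end
                    cds_len = 3 * (len(pep) + 1) if stop_terminated else 3 * len(pep)
                    if cds_len >= min_orf_nt:
                        s = offset + 3 * m + 1          # on the translated strand
                        e = s + cds_len - 1
                        if frame > 0:
                            start_nt, end_nt = s, e
                        else:
                            start_nt, end_nt = L - e + 1, L - s + 1
                        calls.append(
                            OrfCall(
                                transcript_id=record.id,
                                frame=frame,
                                start_nt=start_nt,
                                end_nt=end_nt,
                                peptide=pep,
                                cds_len_nt=cds_len,
                                stop_terminated=stop_terminated,
                            )
                        )
                seg_start = i + 1
            i += 1
    return calls


def best_orf_per_transcript(calls: list[OrfCall]) -> dict[str, OrfCall]:
    """Keep the single longest ORF per transcript.

    Ties break by frame order +1,+2,+3,-1,-2,-3, then by smaller start
    coordinate.
    """
    best: dict[str, OrfCall] = {}
    for call in calls:
        cur = best.get(call.transcript_id)
        if cur is None or _rank(call) < _rank(cur):
            best[call.transcript_id] = call
    return best


def _rank(call: OrfCall) -> tuple[int, int, int]:
    return (-call.cds_len_nt, FRAME_ORDER.index(call.frame), call.start_nt)


def orf_peptides(best: dict[str, OrfCall]) -> list[ProteinRecord]:
    """Protein records for the best ORF of each transcript, in id order."""
    return [
        ProteinRecord(id=tid, seq=call.peptide)
        for tid, call in sorted(best.items())
    ]
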