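"""Readers and writers for the plain-text formats the pipeline consumes,
plus the shared record types used across modules.

Formats handled: FASTA (wrapped or unwrapped, optionally gzipped), the
12-column tab-separated homology-hit layout (BLAST ``-outfmt 6``), the
abundance table shape emitted by pseudoalignment quantifiers
(``target_id  length  eff_length  est_counts  tpm``), and a four-column
GO annotation table (``transcript_id  go_id  category  description``).

Organism labels are parsed from FASTA headers when present: a trailing
bracketed suffix ``[Organism name]`` takes precedence, then a
``taxon=...`` key=value token; otherwise the tag is left empty.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

__all__ = [
    "TranscriptRecord",
    "ProteinRecord",
    "AnnotationRecord",
    "AbundanceRecord",
    "HomologyHit",
    "SeqFormatError",
    "read_fasta",
    "write_fasta",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_abundance",
    "write_abundance",
    "read_annotations",
    "write_annotations",
]

PathLike = Union[str, Path]

_NUC_ALPHABET = frozenset("ACGTN")
# 20 standard residues plus ambiguity X and stop *
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
_GO_PATTERN = re.compile(r"^GO:\d{7}$")
_BRACKET_TAXON = re.compile(r"\[([^\[\]]+)\]\s*$")
_GO_CATEGORIES = frozenset({"BP", "MF", "CC"})


class SeqFormatError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass
class TranscriptRecord:
    """An assembled transcript contig: nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str
    taxon_tag: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.id:
            raise SeqFormatError("transcript record with empty id")
        if not self.seq:
            raise SeqFormatError(f"transcript {self.id!r} has an empty sequence")
        bad = set(self.seq) - _NUC_ALPHABET
        if bad:
            raise SeqFormatError(
                f"transcript {self.id!r} contains non-nucleotide characters: {sorted(bad)}"
            )

    @property
    def length_nt(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """A reference peptide. Internal stop characters are rejected; a single
    trailing ``*`` (common in gene-model exports) is stripped on ingest."""

    id: str
    seq: str
    taxon_tag: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.seq.endswith("*"):
            self.seq = self.seq[:-1]
        if not self.id:
            raise SeqFormatError("protein record with empty id")
        if not self.seq:
            raise SeqFormatError(f"protein {self.id!r} has an empty sequence")
        if "*" in self.seq:
            raise SeqFormatError(f"protein {self.id!r} contains an internal stop")
        bad = set(self.seq) - _AA_ALPHABET
        if bad:
            raise SeqFormatError(
                f"protein {self.id!r} contains non-amino-acid characters: {sorted(bad)}"
            )

    @property
    def length_aa(self) -> int:
        return len(self.seq)


@dataclass
class AnnotationRecord:
    """GO terms attached to one transcript; ``terms`` maps GO id -> category."""

    transcript_id: str
    terms: dict[str, str] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        for go_id, category in self.terms.items():
            if not _GO_PATTERN.match(go_id):
                raise SeqFormatError(f"malformed GO id {go_id!r}")
            if category not in _GO_CATEGORIES:
                raise SeqFormatError(
                    f"GO category for {go_id} must be one of BP/MF/CC, got {category!r}"
                )


@dataclass
class AbundanceRecord:
    """Per-transcript quantifier output: effective length and estimated
    fragment count, with FPKM populated downstream."""

    transcript_id: str
    eff_length_nt: float
    est_count: float
    length_nt: int | None = None
    tpm: float | None = None
    fpkm: float | None = None

    def __post_init__(self) -> None:
        if self.eff_length_nt <= 0:
            raise SeqFormatError(
                f"abundance record {self.transcript_id!r}: effective length must be > 0"
            )
        if self.est_count < 0:
            raise SeqFormatError(
                f"abundance record {self.transcript_id!r}: negative estimated count"
            )


@dataclass
class HomologyHit:
    """One translated-search alignment in the 12-column tabular layout.

    ``frame`` and ``raw_score`` are populated by the built-in search engine
    and default to 0/None when hits are imported from external tabular files.
    """

    query_id: str
    subject_id: str
    pident: float
    align_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    frame: int = 0
    raw_score: int | None = None

    def to_tabular(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.pident:.2f}",
                str(self.align_len),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.qstart),
                str(self.qend),
                str(self.sstart),
                str(self.send),
                f"{self.evalue:.3g}",
                f"{self.bitscore:.1f}",
            ]
        )


def _open_text(path: PathLike, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _parse_taxon(description: str) -> str:
    m = _BRACKET_TAXON.search(description)
    if m:
        return m.group(1)
    for token in description.split():
        if token.startswith("taxon="):
            return token[len("taxon="):].replace("_", " ")
    return ""


def read_fasta(path: PathLike, kind: str = "nucleotide"):
    """Read a FASTA file into an ordered list of records.

    Parameters
    ----------
    path:
        FASTA file, plain or gzipped, wrapped or unwrapped.
    kind:
        ``"nucleotide"`` yields :class:`TranscriptRecord`, ``"protein"``
        yields :class:`ProteinRecord`.

    Raises
    ------
    SeqFormatError
        On a missing leading ``>``, an empty sequence, or a duplicate id.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError(f"kind must be 'nucleotide' or 'protein', got {kind!r}")
    cls = TranscriptRecord if kind == "nucleotide" else ProteinRecord

    records = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        fields = header.split(None, 1)
        rec_id = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        if rec_id in seen:
            raise SeqFormatError(f"duplicate record id {rec_id!r} in {path}")
        seen.add(rec_id)
        records.append(
            cls(id=rec_id, seq="".join(chunks), taxon_tag=_parse_taxon(desc), description=desc)
        )

    with _open_text(path) as handle:
        for raw in handle:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise SeqFormatError(f"empty FASTA header in {path}")
                chunks = []
            else:
                if header is None:
                    raise SeqFormatError(
                        f"{path}: sequence data before the first '>' header"
                    )
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Iterable[TranscriptRecord | ProteinRecord], path: PathLike,
                width: int = 60) -> None:
    """Write records as wrapped FASTA; the taxon tag is re-emitted as a
    bracketed suffix so a read/write round trip preserves it."""
    with _open_text(path, "wt") as handle:
        for rec in records:
            desc = rec.description
            if rec.taxon_tag and f"[{rec.taxon_tag}]" not in desc and "taxon=" not in desc:
                desc = (desc + f" [{rec.taxon_tag}]").strip()
            header = f">{rec.id} {desc}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i:i + width] + "\n")


def read_tabular_hits(path: PathLike) -> list[HomologyHit]:
    """Read homology hits from the 12-column tab-separated layout."""
    hits: list[HomologyHit] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise SeqFormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(cols)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pident=float(cols[2]),
                        align_len=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        qstart=int(cols[6]),
                        qend=int(cols[7]),
                        sstart=int(cols[8]),
                        send=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise SeqFormatError(f"{path}:{lineno}: unparseable numeric field ({exc})")
    return hits


def write_tabular_hits(hits: Iterable[HomologyHit], path: PathLike) -> None:
    with _open_text(path, "wt") as handle:
        for hit in hits:
            handle.write(hit.to_tabular() + "\n")


_ABUNDANCE_HEADER = ["target_id", "length", "eff_length", "est_counts", "tpm"]


def read_abundance(path: PathLike) -> list[AbundanceRecord]:
    """Read a quantifier abundance table (header row required)."""
    records: list[AbundanceRecord] = []
    with _open_text(path) as handle:
        header = handle.readline()
        if not header:
            raise SeqFormatError(f"{path}: empty abundance file (header row required)")
        cols = header.rstrip("\n").split("\t")
        if len(cols) < 4:
            raise SeqFormatError(
                f"{path}: abundance header must have >= 4 tab-separated columns"
            )
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            vals = line.split("\t")
            if len(vals) != len(cols):
                raise SeqFormatError(
                    f"{path}:{lineno}: expected {len(cols)} columns, got {len(vals)}"
                )
            try:
                length = int(float(vals[1]))
                eff_length = float(vals[2])
                est = float(vals[3])
                tpm = float(vals[4]) if len(vals) > 4 else None
            except ValueError as exc:
                raise SeqFormatError(f"{path}:{lineno}: unparseable numeric field ({exc})")
            if length < 0:
                raise SeqFormatError(f"{path}:{lineno}: negative length")
            records.append(
                AbundanceRecord(
                    transcript_id=vals[0],
                    eff_length_nt=eff_length,
                    est_count=est,
                    length_nt=length,
                    tpm=tpm,
                )
            )
    return records


def write_abundance(records: Iterable[AbundanceRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("\t".join(_ABUNDANCE_HEADER) + "\n")
        for rec in records:
            handle.write(
                "\t".join(
                    [
                        rec.transcript_id,
                        str(rec.length_nt if rec.length_nt is not None else ""),
                        f"{rec.eff_length_nt:g}",
                        f"{rec.est_count:g}",
                        f"{rec.tpm:g}" if rec.tpm is not None else "0",
                    ]
                )
                + "\n"
            )


def read_annotations(path: PathLike) -> dict[str, AnnotationRecord]:
    """Read a GO annotation table (transcript_id, go_id, category, description),
    one term per row, aggregated per transcript."""
    table: dict[str, AnnotationRecord] = {}
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols and cols[0] == "transcript_id":
                continue
            if len(cols) < 3:
                raise SeqFormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            tid, go_id, category = cols[0], cols[1], cols[2]
            desc = cols[3] if len(cols) > 3 else ""
            if not _GO_PATTERN.match(go_id):
                raise SeqFormatError(f"{path}:{lineno}: malformed GO id {go_id!r}")
            if category not in _GO_CATEGORIES:
                raise SeqFormatError(f"{path}:{lineno}: bad GO category {category!r}")
            rec = table.setdefault(tid, AnnotationRecord(transcript_id=tid))
            rec.terms[go_id] = category
            if desc and not rec.description:
                rec.description = desc
    return table


def write_annotations(table: Mapping[str, AnnotationRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("transcript_id\tgo_id\tcategory\tdescription\n")
        for tid in sorted(table):
            rec = table[tid]
            for go_id in sorted(rec.terms):
                handle.write(
                    f"{tid}\t{go_id}\t{rec.terms[go_id]}\t{rec.description}\n"
                )
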