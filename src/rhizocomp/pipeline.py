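"""End-to-end pipeline: ORF gating, quantification, the two reference
searches, contamination and expression filtering, the presence/absence
partition, candidate extraction and GO enrichment — with a reproducible
run directory and machine-readable accounting.

Every output is deterministic for a fixed config and inputs: records are
written in sorted order, floats with fixed formats, and nothing
time-dependent enters any file, so a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .abundance import (compute_fpkm, count_fragments, expression_filter,
                        records_from_counts)
from .comparative import (CandidateSet, VennPartition, contamination_filter,
                          partition_accounting, select_candidates,
                          venn_partition)
from .enrichment import enrich
from .homology import ScoringScheme, search, top_hits_by_query
from .orfscan import best_orf_per_transcript, find_orfs, reverse_complement
from .seqio import (TranscriptRecord, read_abundance,
                    read_annotations, read_fasta, read_tabular_hits,
                    write_abundance, write_fasta, write_tabular_hits)
from .stats import AssemblyStats, summarize

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds, scoring constants and input paths for one run."""

    focal_fasta: str
    annual_db: str
    rhizomatous_db: str
    rhizome_assembly: str
    reads_fasta: str | None = None
    abundance_tsv: str | None = None
    nr_db: str | None = None
    nr_hits_tsv: str | None = None
    annual_hits_tsv: str | None = None
    rhizomatous_hits_tsv: str | None = None
    annotations_tsv: str | None = None

    evalue_cutoff: float = 1e-20
    min_fpkm: float = 1.0
    min_orf_nt: int = 297
    match_mode: str = "top"
    plant_taxa: list[str] = field(default_factory=list)
    fragment_length: int = 100
    seeded_search: bool = False

    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    k_: float = 0.041

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0 or self.min_fpkm < 0 or self.min_orf_nt < 3:
            raise ValueError("thresholds must be positive")
        if self.abundance_tsv is None and self.reads_fasta is None:
            raise ValueError("either an abundance table or a reads FASTA "
                             "must be supplied")

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme(gap_open=self.gap_open, gap_extend=self.gap_extend,
                             lambda_=self.lambda_, k_=self.k_)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config file; relative paths resolve against its folder."""
        path = Path(path)
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        base = path.parent
        for key, value in list(data.items()):
            if (key.endswith(("_fasta", "_db", "_tsv", "_assembly"))
                    and isinstance(value, str)):
                data[key] = str((base / value).resolve()
                                if not Path(value).is_absolute() else value)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    contig_stats: AssemblyStats
    cds_stats: AssemblyStats
    coding_ids: frozenset[str]
    fpkm: dict[str, float]
    expression_kept: frozenset[str]
    expression_removed: frozenset[str]
    contamination_kept: frozenset[str]
    contamination_removed: frozenset[str]
    partition: VennPartition
    accounting: dict
    candidates: CandidateSet
    background_ids: frozenset[str]
    enrichment: list
    outdir: Path


def _extract_cds(record: TranscriptRecord, call) -> str:
    segment = record.seq[call.start_nt - 1:call.end_nt]
    return reverse_complement(segment) if call.frame < 0 else segment


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Execute the full analysis and write the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(msg: str) -> None:
        log.append(msg)

    scheme = config.scheme

    # --- inputs -----------------------------------------------------------
    contigs = read_fasta(config.focal_fasta, kind="nucleotide")
    annual_db = read_fasta(config.annual_db, kind="protein")
    rhiz_db = read_fasta(config.rhizomatous_db, kind="protein")
    rhizome_contigs = read_fasta(config.rhizome_assembly, kind="nucleotide")
    stage(f"inputs: {len(contigs)} focal contigs, {len(annual_db)} annual "
          f"proteins, {len(rhiz_db)} rhizomatous proteins, "
          f"{len(rhizome_contigs)} rhizome-assembly contigs")

    # --- coding-region gate ----------------------------------------------
    calls = []
    for rec in contigs:
        calls.extend(find_orfs(rec, config.min_orf_nt))
    best = best_orf_per_transcript(calls)
    coding_ids = frozenset(best)
    coding = [rec for rec in contigs if rec.id in coding_ids]
    stage(f"coding gate (min ORF {config.min_orf_nt} nt): "
          f"{len(coding)} of {len(contigs)} contigs retained")

    by_id = {rec.id: rec for rec in contigs}
    cds_records = [
        TranscriptRecord(id=tid, seq=_extract_cds(by_id[tid], call))
        for tid, call in sorted(best.items())
    ]
    contig_stats = summarize(contigs)
    cds_stats = summarize(cds_records)

    # --- quantification and expression filter ----------------------------
    if config.abundance_tsv:
        ab_records = read_abundance(config.abundance_tsv)
    else:
        reads = [rec.seq for rec in
                 read_fasta(config.reads_fasta, kind="nucleotide")]
        counts = count_fragments(reads, contigs)
        ab_records = records_from_counts(counts, contigs, config.fragment_length)
    compute_fpkm(ab_records)
    fpkm = {rec.transcript_id: rec.fpkm for rec in ab_records}
    coding_ab = [rec for rec in ab_records if rec.transcript_id in coding_ids]
    missing = coding_ids - set(fpkm)
    if missing:
        stage(f"warning: {len(missing)} coding contigs absent from the "
              "abundance table; treated as unexpressed")
    expr_kept, expr_removed = expression_filter(coding_ab, config.min_fpkm)
    expr_removed |= missing
    stage(f"expression filter (FPKM >= {config.min_fpkm:g}): "
          f"{len(expr_kept)} kept, {len(expr_removed)} removed")

    # --- reference searches ----------------------------------------------
    if config.annual_hits_tsv:
        hits_annual = read_tabular_hits(config.annual_hits_tsv)
        hits_annual = [h for h in hits_annual if h.evalue < config.evalue_cutoff]
    else:
        hits_annual = search(coding, annual_db, scheme,
                             evalue_cutoff=config.evalue_cutoff,
                             seeded=config.seeded_search)
    if config.rhizomatous_hits_tsv:
        hits_rhiz = read_tabular_hits(config.rhizomatous_hits_tsv)
        hits_rhiz = [h for h in hits_rhiz if h.evalue < config.evalue_cutoff]
    else:
        hits_rhiz = search(coding, rhiz_db, scheme,
                           evalue_cutoff=config.evalue_cutoff,
                           seeded=config.seeded_search)
    stage(f"reference searches at E < {config.evalue_cutoff:g}: "
          f"{len(hits_annual)} annual hits, {len(hits_rhiz)} rhizomatous hits")

    # rhizome-expressed reference peptides: top hits of the rhizome assembly
    rhizome_hits = search(rhizome_contigs, rhiz_db, scheme,
                          evalue_cutoff=config.evalue_cutoff,
                          seeded=config.seeded_search)
    rhizome_subjects = frozenset(
        h.subject_id for h in top_hits_by_query(rhizome_hits).values()
    )
    stage(f"rhizome assembly: {len(rhizome_subjects)} reference peptides "
          "evidenced as rhizome-expressed")

    # --- contamination filter --------------------------------------------
    subject_taxa: dict[str, str] = {}
    hits_nr = []
    if config.nr_hits_tsv:
        hits_nr = read_tabular_hits(config.nr_hits_tsv)
        if config.nr_db:
            nr_db = read_fasta(config.nr_db, kind="protein")
            subject_taxa = {p.id: p.taxon_tag for p in nr_db}
    elif config.nr_db:
        nr_db = read_fasta(config.nr_db, kind="protein")
        subject_taxa = {p.id: p.taxon_tag for p in nr_db}
        hits_nr = search(coding, nr_db, scheme,
                         evalue_cutoff=config.evalue_cutoff,
                         seeded=config.seeded_search)
    if hits_nr and config.plant_taxa:
        contam_kept, contam_removed = contamination_filter(
            coding_ids, hits_nr, config.plant_taxa, subject_taxa
        )
    else:
        contam_kept, contam_removed = set(coding_ids), set()
        stage("contamination filter skipped: no annotated search supplied")
    stage(f"contamination filter: {len(contam_kept)} kept, "
          f"{len(contam_removed)} removed")
    nr_tops = top_hits_by_query(hits_nr)
    top_taxon = {q: subject_taxa.get(h.subject_id, "")
                 for q, h in nr_tops.items()}

    # --- partition and candidates ----------------------------------------
    partition = venn_partition(coding_ids, hits_annual, hits_rhiz,
                               rhizome_subjects, config.match_mode)
    accounting_part = partition_accounting(partition)
    rhiz_tops = top_hits_by_query(hits_rhiz)
    rhiz_top_subject = {q: h.subject_id for q, h in rhiz_tops.items()}
    candidates = select_candidates(
        partition, fpkm, contam_kept, config.min_fpkm,
        rhiz_top_subject=rhiz_top_subject, top_hit_taxon=top_taxon,
    )
    stage(f"partition: {accounting_part}")
    stage(f"candidates: {len(candidates.candidate_ids)} contigs, "
          f"{len(candidates.unique_subjects)} unique reference peptides")

    # --- enrichment -------------------------------------------------------
    background = frozenset(coding_ids & expr_kept & contam_kept)
    enrichment_results = []
    if config.annotations_tsv:
        annotations = read_annotations(config.annotations_tsv)
        enrichment_results = enrich(candidates.candidate_ids, background,
                                    annotations)
        stage(f"enrichment: {len(enrichment_results)} GO terms tested "
              f"against a background of {len(background)}")

    # --- accounting with arithmetic identities ----------------------------
    accounting = {
        "n_contigs": len(contigs),
        "n_coding": len(coding_ids),
        "n_noncoding": len(contigs) - len(coding_ids),
        "expression_kept": len(expr_kept),
        "expression_removed": len(expr_removed),
        "contamination_kept": len(contam_kept),
        "contamination_removed": len(contam_removed),
        "filtered_assembly": len(background),
        "partition": accounting_part,
        "candidate_pool": len(partition.only_rhiz_in_rhizome_assembly),
        "candidates": len(candidates.candidate_ids),
        "unique_subjects": len(candidates.unique_subjects),
    }
    _assert_identities(accounting)

    # --- write the run directory -----------------------------------------
    _write_outputs(outdir, config, contigs, cds_records, best, ab_records,
                   hits_annual, hits_rhiz, hits_nr, contig_stats, cds_stats,
                   accounting, candidates, enrichment_results, log)

    return PipelineResult(
        contig_stats=contig_stats,
        cds_stats=cds_stats,
        coding_ids=coding_ids,
        fpkm=fpkm,
        expression_kept=frozenset(expr_kept),
        expression_removed=frozenset(expr_removed),
        contamination_kept=frozenset(contam_kept),
        contamination_removed=frozenset(contam_removed),
        partition=partition,
        accounting=accounting,
        candidates=candidates,
        background_ids=background,
        enrichment=enrichment_results,
        outdir=outdir,
    )


def _assert_identities(acc: dict) -> None:
    """Every filter step must conserve records: input = kept + removed."""
    part = acc["partition"]
    checks = [
        acc["n_contigs"] == acc["n_coding"] + acc["n_noncoding"],
        acc["n_coding"] == acc["expression_kept"] + acc["expression_removed"],
        acc["n_coding"] == acc["contamination_kept"] + acc["contamination_removed"],
        part["total"] == acc["n_coding"],
        part["total"] == (part["both"] + part["only_annual"]
                          + part["only_rhiz_not_in_rhizome_assembly"]
                          + part["only_rhiz_in_rhizome_assembly"]
                          + part["none"]),
        part["with_annual_hit"] == part["both"] + part["only_annual"],
        part["with_rhizomatous_hit"] == part["both"] + part["only_rhizomatous"],
        part["only_rhizomatous"] == (part["only_rhiz_not_in_rhizome_assembly"]
                                     + part["only_rhiz_in_rhizome_assembly"]),
        acc["candidates"] <= acc["candidate_pool"],
        acc["unique_subjects"] <= acc["candidates"],
    ]
    if not all(checks):
        raise AssertionError(f"accounting identity violated: {acc}")


def _partition_report(acc: dict) -> str:
    part = acc["partition"]
    rows = [
        ("Total number of query sequences", part["total"]),
        ("Sequences with >= 1 hit from the annual reference",
         part["with_annual_hit"]),
        ("Sequences with >= 1 hit from the rhizomatous reference",
         part["with_rhizomatous_hit"]),
        ("Sequences with >= 1 hit from both organisms", part["both"]),
        ("Sequences with no hits", part["none"]),
        ("Sequences with >= 1 hit from only the annual reference",
         part["only_annual"]),
        ("Sequences with >= 1 hit from only the rhizomatous reference",
         part["only_rhizomatous"]),
        ("Sequences with >= 1 hit from only the rhizomatous reference "
         "and in the rhizome assembly", part["only_rhiz_in_rhizome_assembly"]),
        ("Sequences from above with FPKM >= threshold and a plant top hit",
         acc["candidates"]),
    ]
    return "\n".join(f"{name}\t{value:,}" for name, value in rows) + "\n"


def _write_outputs(outdir: Path, config: PipelineConfig,
                   contigs, cds_records, best, ab_records,
                   hits_annual, hits_rhiz, hits_nr,
                   contig_stats, cds_stats, accounting,
                   candidates: CandidateSet, enrichment_results,
                   log: Sequence[str]) -> None:
    with open(outdir / "stats.tsv", "w") as handle:
        handle.write("section\tmetric\tvalue\n")
        for name, value in contig_stats.report_rows():
            handle.write(f"contigs\t{name}\t{value}\n")
        for name, value in cds_stats.report_rows():
            handle.write(f"coding_sequences\t{name}\t{value}\n")

    write_fasta(cds_records, outdir / "coding.fasta")
    with open(outdir / "orfs.tsv", "w") as handle:
        handle.write("transcript_id\tframe\tstart_nt\tend_nt\tcds_len_nt\t"
                     "stop_terminated\n")
        for tid in sorted(best):
            call = best[tid]
            handle.write(f"{tid}\t{call.frame:+d}\t{call.start_nt}\t"
                         f"{call.end_nt}\t{call.cds_len_nt}\t"
                         f"{int(call.stop_terminated)}\n")

    write_abundance(sorted(ab_records, key=lambda r: r.transcript_id),
                    outdir / "abundance.tsv")
    write_tabular_hits(hits_annual, outdir / "hits_annual.tsv")
    write_tabular_hits(hits_rhiz, outdir / "hits_rhizomatous.tsv")
    if hits_nr:
        write_tabular_hits(hits_nr, outdir / "hits_nr.tsv")

    (outdir / "partition.tsv").write_text(_partition_report(accounting))

    by_id = {rec.id: rec for rec in contigs}
    write_fasta([by_id[q] for q in sorted(candidates.candidate_ids)],
                outdir / "candidates.fasta")
    with open(outdir / "candidates.tsv", "w") as handle:
        handle.write("transcript_id\tfpkm\ttop_hit_taxon\trhizomatous_subject\n")
        for qid in sorted(candidates.candidate_ids):
            prov = candidates.provenance[qid]
            handle.write(f"{qid}\t{prov['fpkm']:.4f}\t{prov['top_hit_taxon']}\t"
                         f"{prov['rhizomatous_subject']}\n")
    (outdir / "unique_subjects.txt").write_text(
        "".join(s + "\n" for s in sorted(candidates.unique_subjects))
    )

    if enrichment_results:
        with open(outdir / "enrichment.tsv", "w") as handle:
            handle.write("go_id\tcategory\ta\tb\tc\td\tdirection\tp_value\t"
                         "fdr_q\n")
            for res in enrichment_results:
                handle.write(res.to_row() + "\n")

    (outdir / "accounting.json").write_text(
        json.dumps(accounting, indent=2, sort_keys=True) + "\n"
    )
    manifest = {
        "package": "rhizocomp",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_counts": {k: v for k, v in accounting.items()
                         if not isinstance(v, dict)},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "run.log").write_text("".join(line + "\n" for line in log))
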