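"""Three-taxon synthetic transcriptome system with planted truth.

The generator emulates the comparative setting the pipeline targets: a
focal rhizomatous species (transcript contigs + sequencing fragments),
an annual reference relative (proteome), a rhizomatous reference
relative (proteome plus a rhizome-tissue transcript assembly), and a
combined organism-labelled protein database standing in for a
comprehensive annotation database. Genes fall into six classes:

* ``core`` — present in all three taxa (and rhizome-expressed);
* ``rhizome_specific`` — present in both rhizomatous lineages and in the
  rhizome assembly, absent from the annual reference: the planted truth
  the pipeline should recover;
* ``annual_only`` — shared by the focal species and the annual reference
  only;
* ``focal_private`` — focal contigs with no homolog anywhere;
* ``contaminant`` — focal contigs of non-plant origin whose top hit in
  the labelled database is a non-plant organism;
* ``low_expression_noise`` — contigs with the same presence/absence
  profile as ``rhizome_specific`` but without fragment support, so only
  the expression filter separates them from true candidates.

Each gene starts from an ancestral peptide; per-taxon copies mutate at a
configurable per-site amino-acid rate and are back-translated with
uniform codon choice, so divergence maps directly onto alignment-score
decay. All randomness flows through one seeded generator: the same
config and seed reproduce every output byte-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .abundance import effective_length
from .orfscan import _CODON_TABLE, reverse_complement
from .seqio import (AnnotationRecord, ProteinRecord, TranscriptRecord,
                    write_annotations, write_fasta)

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticDataset",
           "generate", "truth_metrics", "CLASS_LABELS"]

CLASS_LABELS = ("core", "rhizome_specific", "annual_only", "focal_private",
                "contaminant", "low_expression_noise")

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_FOR: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_CODON_TABLE.items()):
    if _aa != "*":
        _CODONS_FOR.setdefault(_aa, ())
        _CODONS_FOR[_aa] = _CODONS_FOR[_aa] + (_codon,)
_STOP_CODONS = tuple(sorted(c for c, a in _CODON_TABLE.items() if a == "*"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic system.

    Defaults give a 200-gene desk-scale system: mean coding length 900 nt
    and 50-200 sequencing fragments per expressed gene. Divergence rates
    are per-site amino-acid substitution probabilities applied to each
    taxon's copy of the ancestral peptide.
    """

    n_core: int = 150
    n_rhizome_specific: int = 20
    n_annual_only: int = 10
    n_focal_private: int = 5
    n_contaminant: int = 5
    n_low_expression: int = 10

    mean_cds_nt: float = 900.0
    sd_cds_nt: float = 180.0
    min_cds_nt: int = 360

    divergence_focal: float = 0.05
    divergence_annual: float = 0.05
    divergence_rhizomatous: float = 0.05

    utr_min_nt: int = 30
    utr_max_nt: int = 90
    fragment_length: int = 100
    min_fragments: int = 50
    max_fragments: int = 200

    n_background_go_terms: int = 20
    go_terms_per_transcript: int = 3
    planted_go_term: str = "GO:0009834"
    planted_term_candidate_freq: float = 0.9
    planted_term_background_freq: float = 0.05

    focal_taxon: str = "Sorghum halepense"
    annual_taxon: str = "Sorghum bicolor"
    rhizomatous_taxon: str = "Thinopyrum intermedium"
    contaminant_taxon: str = "Fusarium oxysporum"

    def __post_init__(self) -> None:
        counts = (self.n_core, self.n_rhizome_specific, self.n_annual_only,
                  self.n_focal_private, self.n_contaminant, self.n_low_expression)
        if any(c < 0 for c in counts):
            raise ValueError("gene counts must be non-negative")
        for rate in (self.divergence_focal, self.divergence_annual,
                     self.divergence_rhizomatous):
            if not 0.0 <= rate < 0.5:
                raise ValueError("divergence rates must lie in [0, 0.5)")
        if self.min_cds_nt % 3 != 0 or self.min_cds_nt < 150:
            raise ValueError("min_cds_nt must be a multiple of 3 and >= 150")
        if self.fragment_length < 20:
            raise ValueError("fragment_length must be >= 20")

    @property
    def n_genes(self) -> int:
        return (self.n_core + self.n_rhizome_specific + self.n_annual_only
                + self.n_focal_private + self.n_contaminant
                + self.n_low_expression)

    @property
    def plant_taxa(self) -> tuple[str, str, str]:
        return (self.focal_taxon, self.annual_taxon, self.rhizomatous_taxon)

    @classmethod
    def noiseless(cls, **overrides) -> "SyntheticConfig":
        """The fully separable small system: 10 core, 5 rhizome-specific,
        3 annual-only, 3 contaminant and 4 low-expression genes with zero
        sequence divergence."""
        params = dict(
            n_core=10, n_rhizome_specific=5, n_annual_only=3,
            n_focal_private=0, n_contaminant=3, n_low_expression=4,
            divergence_focal=0.0, divergence_annual=0.0,
            divergence_rhizomatous=0.0,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-gene labels and expression levels for one run."""

    classes: dict[str, str]          # focal contig id -> class label
    planted_fpkm: dict[str, float]   # focal contig id -> fpkm implied by counts
    divergence: dict[str, float]
    seed: int

    def ids_of(self, label: str) -> frozenset[str]:
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r}")
        return frozenset(t for t, c in self.classes.items() if c == label)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "divergence": self.divergence,
                "classes": dict(sorted(self.classes.items())),
                "planted_fpkm": {k: round(v, 6)
                                 for k, v in sorted(self.planted_fpkm.items())},
            },
            indent=2, sort_keys=True,
        )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: SyntheticTruth
    focal_contigs: list[TranscriptRecord]
    annual_proteins: list[ProteinRecord]
    rhizomatous_proteins: list[ProteinRecord]
    rhizome_assembly: list[TranscriptRecord]
    nr_proteins: list[ProteinRecord]
    reads: list[str]
    annotations: dict[str, AnnotationRecord]

    def write(self, outdir) -> dict[str, Path]:
        """Write every artifact (plus a ready-to-run pipeline config) and
        return the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "focal_fasta": outdir / "focal_contigs.fasta",
            "annual_db": outdir / "annual_proteins.fasta",
            "rhizomatous_db": outdir / "rhizomatous_proteins.fasta",
            "rhizome_assembly": outdir / "rhizome_assembly.fasta",
            "nr_db": outdir / "nr_proteins.fasta",
            "reads_fasta": outdir / "reads.fasta",
            "annotations_tsv": outdir / "annotations.tsv",
            "truth_json": outdir / "truth.json",
            "pipeline_yaml": outdir / "pipeline.yaml",
        }
        write_fasta(self.focal_contigs, paths["focal_fasta"])
        write_fasta(self.annual_proteins, paths["annual_db"])
        write_fasta(self.rhizomatous_proteins, paths["rhizomatous_db"])
        write_fasta(self.rhizome_assembly, paths["rhizome_assembly"])
        write_fasta(self.nr_proteins, paths["nr_db"])
        with open(paths["reads_fasta"], "w") as handle:
            for i, read in enumerate(self.reads):
                handle.write(f">read_{i:06d}\n{read}\n")
        write_annotations(self.annotations, paths["annotations_tsv"])
        paths["truth_json"].write_text(self.truth.to_json() + "\n")
        pipeline_cfg = {
            "focal_fasta": "focal_contigs.fasta",
            "annual_db": "annual_proteins.fasta",
            "rhizomatous_db": "rhizomatous_proteins.fasta",
            "rhizome_assembly": "rhizome_assembly.fasta",
            "nr_db": "nr_proteins.fasta",
            "reads_fasta": "reads.fasta",
            "annotations_tsv": "annotations.tsv",
            "plant_taxa": list(self.config.plant_taxa),
            "fragment_length": self.config.fragment_length,
        }
        with open(paths["pipeline_yaml"], "w") as handle:
            yaml.safe_dump(pipeline_cfg, handle, sort_keys=True)
        return paths


def _random_peptide(rng: np.random.Generator, length_aa: int) -> str:
    body = rng.integers(0, len(_AA20), size=length_aa - 1)
    return "M" + "".join(_AA20[i] for i in body)


def _mutate(rng: np.random.Generator, peptide: str, rate: float) -> str:
    """Substitute each site after the initiator with probability ``rate``;
    the leading methionine is preserved so the reading frame stays open."""
    if rate <= 0.0:
        return peptide
    chars = list(peptide)
    hit = rng.random(len(chars) - 1) < rate
    for offset in np.nonzero(hit)[0]:
        i = int(offset) + 1
        choices = [a for a in _AA20 if a != chars[i]]
        chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def _back_translate(rng: np.random.Generator, peptide: str,
                    add_stop: bool = True) -> str:
    codons = []
    for aa in peptide:
        options = _CODONS_FOR[aa]
        codons.append(options[rng.integers(0, len(options))])
    if add_stop:
        codons.append(_STOP_CODONS[rng.integers(0, len(_STOP_CODONS))])
    return "".join(codons)


def _random_utr(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _contig(rng: np.random.Generator, peptide: str, cfg: SyntheticConfig) -> str:
    return (_random_utr(rng, cfg.utr_min_nt, cfg.utr_max_nt)
            + _back_translate(rng, peptide)
            + _random_utr(rng, cfg.utr_min_nt, cfg.utr_max_nt))


def generate(config: SyntheticConfig | None = None, seed: int = 42,
             outdir=None) -> SyntheticDataset:
    """Build the full synthetic system; optionally write it to ``outdir``."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)

    labels: list[str] = (
        ["core"] * cfg.n_core
        + ["rhizome_specific"] * cfg.n_rhizome_specific
        + ["annual_only"] * cfg.n_annual_only
        + ["focal_private"] * cfg.n_focal_private
        + ["contaminant"] * cfg.n_contaminant
        + ["low_expression_noise"] * cfg.n_low_expression
    )
    if not labels:
        raise ValueError("configuration generates no genes at all")

    min_aa = cfg.min_cds_nt // 3
    focal_contigs: list[TranscriptRecord] = []
    annual_proteins: list[ProteinRecord] = []
    rhiz_proteins: list[ProteinRecord] = []
    rhizome_assembly: list[TranscriptRecord] = []
    contaminant_proteins: list[ProteinRecord] = []
    classes: dict[str, str] = {}

    for gi, label in enumerate(labels):
        length_aa = max(min_aa, int(round(rng.normal(cfg.mean_cds_nt / 3.0,
                                                     cfg.sd_cds_nt / 3.0))))
        ancestral = _random_peptide(rng, length_aa)
        focal_id = f"contig_{gi:04d}"
        classes[focal_id] = label

        focal_pep = _mutate(rng, ancestral, cfg.divergence_focal)
        focal_contigs.append(
            TranscriptRecord(id=focal_id, seq=_contig(rng, focal_pep, cfg),
                             taxon_tag=cfg.focal_taxon)
        )
        if label in ("core", "annual_only"):
            annual_pep = _mutate(rng, ancestral, cfg.divergence_annual)
            annual_proteins.append(
                ProteinRecord(id=f"SBIC_{gi:04d}", seq=annual_pep,
                              taxon_tag=cfg.annual_taxon)
            )
        if label in ("core", "rhizome_specific", "low_expression_noise"):
            rhiz_pep = _mutate(rng, ancestral, cfg.divergence_rhizomatous)
            rhiz_proteins.append(
                ProteinRecord(id=f"THIN_{gi:04d}", seq=rhiz_pep,
                              taxon_tag=cfg.rhizomatous_taxon)
            )
            rhizome_assembly.append(
                TranscriptRecord(id=f"trhiz_{gi:04d}",
                                 seq=_contig(rng, rhiz_pep, cfg),
                                 taxon_tag=cfg.rhizomatous_taxon)
            )
        if label == "contaminant":
            contaminant_proteins.append(
                ProteinRecord(id=f"CONT_{gi:04d}", seq=focal_pep,
                              taxon_tag=cfg.contaminant_taxon)
            )

    nr_proteins = annual_proteins + rhiz_proteins + contaminant_proteins

    # fragment counts: expressed genes draw uniformly from the configured
    # range; background-noise genes get no fragment support, so their
    # realised FPKM is 0 and falls below any positive threshold
    frag_counts: dict[str, int] = {}
    for rec in focal_contigs:
        if classes[rec.id] == "low_expression_noise":
            frag_counts[rec.id] = 0
        else:
            frag_counts[rec.id] = int(
                rng.integers(cfg.min_fragments, cfg.max_fragments + 1)
            )

    reads: list[str] = []
    for rec in focal_contigs:
        n_frag = frag_counts[rec.id]
        if n_frag == 0:
            continue
        span = rec.length_nt - cfg.fragment_length
        if span < 0:
            raise ValueError(
                f"contig {rec.id} shorter than the fragment length"
            )
        starts = rng.integers(0, span + 1, size=n_frag)
        flips = rng.random(n_frag) < 0.5
        for start, flip in zip(starts, flips):
            frag = rec.seq[int(start):int(start) + cfg.fragment_length]
            reads.append(reverse_complement(frag) if flip else frag)

    total = sum(frag_counts.values())
    planted_fpkm = {
        rec.id: frag_counts[rec.id] * 1e9
        / (effective_length(rec.length_nt, cfg.fragment_length) * total)
        for rec in focal_contigs
    }

    annotations = _make_annotations(rng, cfg, focal_contigs, classes)

    truth = SyntheticTruth(
        classes=classes,
        planted_fpkm=planted_fpkm,
        divergence={
            "focal": cfg.divergence_focal,
            "annual": cfg.divergence_annual,
            "rhizomatous": cfg.divergence_rhizomatous,
        },
        seed=seed,
    )
    dataset = SyntheticDataset(
        config=cfg,
        truth=truth,
        focal_contigs=focal_contigs,
        annual_proteins=annual_proteins,
        rhizomatous_proteins=rhiz_proteins,
        rhizome_assembly=rhizome_assembly,
        nr_proteins=nr_proteins,
        reads=reads,
        annotations=annotations,
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset


def _make_annotations(rng: np.random.Generator, cfg: SyntheticConfig,
                      contigs: list[TranscriptRecord],
                      classes: Mapping[str, str]) -> dict[str, AnnotationRecord]:
    categories = ("BP", "MF", "CC")
    pool = [(f"GO:{11000 + i:07d}", categories[i % 3])
            for i in range(cfg.n_background_go_terms)]
    table: dict[str, AnnotationRecord] = {}
    for rec in contigs:
        terms: dict[str, str] = {}
        k = min(cfg.go_terms_per_transcript, len(pool))
        if k:
            for idx in rng.choice(len(pool), size=k, replace=False):
                go_id, cat = pool[int(idx)]
                terms[go_id] = cat
        freq = (cfg.planted_term_candidate_freq
                if classes[rec.id] == "rhizome_specific"
                else cfg.planted_term_background_freq)
        if rng.random() < freq:
            terms[cfg.planted_go_term] = "BP"
        table[rec.id] = AnnotationRecord(transcript_id=rec.id, terms=terms,
                                         description="synthetic annotation")
    return table


def truth_metrics(candidate_ids: Iterable[str], truth: SyntheticTruth,
                  label: str = "rhizome_specific") -> tuple[float, float]:
    """Set precision and recall of a candidate id set against a planted
    class. An empty candidate set has precision 1.0 by convention (no
    false positives); an empty truth class is an error."""
    positives = truth.ids_of(label)
    if not positives:
        raise ValueError(f"truth class {label!r} is empty")
    candidates = set(candidate_ids)
    tp = len(candidates & positives)
    precision = tp / len(candidates) if candidates else 1.0
    recall = tp / len(positives)
    return precision, recall


def config_to_dict(cfg: SyntheticConfig) -> dict:
    return dataclasses.asdict(cfg)
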