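"""Reference data access: genome FASTA, transcript models (GTF), protein
domains and the druggable-kinase gene list.

Internal coordinates are 0-based half-open throughout; GTF input/output
converts from/to the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from Bio.Seq import reverse_complement

from .errors import AnnotationError, CoordinateError, InputFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeSequence",
    "Exon",
    "TranscriptModel",
    "DomainAnnotation",
    "DruggableGeneList",
    "read_genome",
    "read_annotation",
    "write_annotation",
    "spliced_sequence",
    "read_domain_table",
    "read_gene_list",
    "select_transcript",
]


class GenomeSequence:
    """Uppercased nucleotide sequences keyed by contig name.

    Interval queries use 0-based half-open coordinates and are strict:
    a request reaching past the contig end raises :class:`CoordinateError`
    instead of silently truncating.
    """

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeSequence":
        return read_genome(path)

    @property
    def names(self) -> list[str]:
        return list(self._contigs)

    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs

    def length(self, contig: str) -> int:
        self._require(contig)
        return len(self._contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the bases of ``[start, end)`` on ``contig``."""
        self._require(contig)
        seq = self._contigs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise CoordinateError(
                f"interval [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    def _require(self, contig: str) -> None:
        if contig not in self._contigs:
            raise CoordinateError(f"contig {contig!r} not in genome")


def read_genome(path: str | os.PathLike) -> GenomeSequence:
    """Load a (multi-)FASTA file into a :class:`GenomeSequence`.

    Soft-masked lowercase bases are uppercased on load.
    """
    import pyfaidx

    try:
        fasta = pyfaidx.Fasta(
            str(path), sequence_always_upper=True, as_raw=True, rebuild=True
        )
    except (pyfaidx.FastaIndexingError, pyfaidx.FastaNotFoundError, IOError) as exc:
        raise InputFormatError(f"malformed or missing FASTA {path}: {exc}") from exc
    contigs = {name: str(fasta[name][:]) for name in fasta.keys()}
    fasta.close()
    if not contigs:
        raise InputFormatError(f"FASTA {path} contains no records")
    return GenomeSequence(contigs)


@dataclass(frozen=True)
class Exon:
    """One genomic exon interval (0-based half-open) with its transcript rank."""

    start: int
    end: int
    rank: int

    def __post_init__(self):
        if self.end <= self.start:
            raise AnnotationError(f"empty exon interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered exons plus an optional CDS span.

    ``exons`` are in transcript (5'->3') order, ``rank`` starting at 1; for
    minus-strand transcripts genomic starts therefore strictly decrease with
    rank.  ``cds_start``/``cds_end`` are transcript coordinates (0-based
    half-open) of the coding span *including* the stop codon when annotated;
    both are ``None`` for non-coding transcripts.
    """

    gene_id: str
    gene_name: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[Exon, ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        ranks = [e.rank for e in self.exons]
        if ranks != list(range(1, len(ranks) + 1)):
            raise AnnotationError(
                f"exon ranks of {self.transcript_id} not 1..n: {ranks}"
            )
        starts = [e.start for e in self.exons]
        ordered = sorted(starts) if self.strand == "+" else sorted(starts, reverse=True)
        if starts != ordered:
            raise AnnotationError(
                f"exon order of {self.transcript_id} inconsistent with strand"
            )
        ivs = sorted((e.start, e.end) for e in self.exons)
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise AnnotationError(f"overlapping exons in {self.transcript_id}")
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError("cds_start/cds_end must be set together")
        if self.cds_start is not None:
            if not (0 <= self.cds_start < self.cds_end <= self.length):
                raise AnnotationError(
                    f"CDS [{self.cds_start}, {self.cds_end}) outside transcript "
                    f"{self.transcript_id}"
                )
            if (self.cds_end - self.cds_start) % 3 != 0:
                logger.warning(
                    "CDS length of %s not divisible by 3 (annotation may be "
                    "truncated)",
                    self.transcript_id,
                )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def cds_length(self) -> Optional[int]:
        if self.cds_start is None:
            return None
        return self.cds_end - self.cds_start

    def exon(self, rank: int) -> Exon:
        if not 1 <= rank <= self.n_exons:
            raise CoordinateError(
                f"exon rank {rank} outside 1..{self.n_exons} of {self.transcript_id}"
            )
        return self.exons[rank - 1]

    def genomic_to_transcript(self, pos: int) -> int:
        """Transcript offset of the base at genomic coordinate ``pos``.

        ``pos`` must fall inside an exon of this transcript.
        """
        offset = 0
        for ex in self.exons:
            if ex.start <= pos < ex.end:
                if self.strand == "+":
                    return offset + (pos - ex.start)
                return offset + (ex.end - 1 - pos)
            offset += len(ex)
        raise CoordinateError(
            f"genomic position {pos} not exonic in {self.transcript_id}"
        )

    def transcript_to_genomic(self, offset: int) -> int:
        """Genomic coordinate of the base at transcript ``offset``."""
        if not 0 <= offset < self.length:
            raise CoordinateError(
                f"offset {offset} outside transcript {self.transcript_id}"
            )
        cum = 0
        for ex in self.exons:
            if offset < cum + len(ex):
                within = offset - cum
                if self.strand == "+":
                    return ex.start + within
                return ex.end - 1 - within
            cum += len(ex)
        raise AssertionError("unreachable")

    def exon_rank_at_offset(self, offset: int) -> int:
        """Rank of the exon containing transcript ``offset``."""
        if not 0 <= offset < self.length:
            raise CoordinateError(
                f"offset {offset} outside transcript {self.transcript_id}"
            )
        cum = 0
        for ex in self.exons:
            if offset < cum + len(ex):
                return ex.rank
            cum += len(ex)
        raise AssertionError("unreachable")

    def exon_transcript_span(self, rank: int) -> tuple[int, int]:
        """Transcript-coordinate half-open span of exon ``rank``."""
        cum = 0
        for ex in self.exons:
            if ex.rank == rank:
                return cum, cum + len(ex)
            cum += len(ex)
        raise CoordinateError(f"no exon rank {rank} in {self.transcript_id}")


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein domain in 1-based inclusive wild-type residue coordinates."""

    gene_name: str
    domain_name: str
    start_residue: int
    end_residue: int

    def __post_init__(self):
        if not 1 <= self.start_residue <= self.end_residue:
            raise InputFormatError(
                f"invalid domain residues {self.start_residue}..{self.end_residue} "
                f"for {self.gene_name}"
            )


@dataclass(frozen=True)
class DruggableGeneList:
    """Uppercase-normalized gene names, optionally with a drug-class note."""

    genes: frozenset[str]
    notes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.genes:
            raise InputFormatError("druggable gene list is empty")

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


def spliced_sequence(model: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced transcript sequence, reverse-complemented per exon for strand -."""
    if model.contig not in genome:
        raise CoordinateError(
            f"contig {model.contig!r} of {model.transcript_id} missing from genome"
        )
    parts = []
    for ex in model.exons:
        seq = genome.fetch(model.contig, ex.start, ex.end)
        parts.append(seq if model.strand == "+" else reverse_complement(seq))
    return "".join(parts)


# ---------------------------------------------------------------------------
# GTF input / output
# ---------------------------------------------------------------------------

def read_annotation(path: str | os.PathLike) -> list[TranscriptModel]:
    """Parse an Ensembl-dialect GTF into transcript models.

    Exons are grouped per transcript and ordered 5'->3' in transcript
    orientation; the CDS span (including any ``stop_codon`` feature) is
    converted to transcript coordinates.  Transcripts with zero exons are
    skipped with a warning; conflicting strands within one transcript raise.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise InputFormatError(f"malformed GTF {path}: {exc}") from exc

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise InputFormatError(f"feature without transcript_id at line: {feat}")
        info = meta.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", [tid])[0],
                "gene_name": feat.attributes.get(
                    "gene_name", feat.attributes.get("gene_id", [tid])
                )[0],
                "contig": feat.seqid,
                "strand": feat.strand,
            },
        )
        if feat.strand != info["strand"]:
            raise AnnotationError(
                f"conflicting strands within transcript {tid}"
            )
        if feat.seqid != info["contig"]:
            raise AnnotationError(f"transcript {tid} spans multiple contigs")
        # GTF is 1-based inclusive -> 0-based half-open
        iv = (feat.start - 1, feat.end)
        if feat.featuretype == "exon":
            number = feat.attributes.get("exon_number", [None])[0]
            exons.setdefault(tid, []).append((iv, number))
        else:
            cds.setdefault(tid, []).append(iv)

    models = []
    for tid, info in meta.items():
        raw = exons.get(tid, [])
        if not raw:
            logger.warning("transcript %s has zero exons; skipped", tid)
            continue
        if all(num is not None for _, num in raw):
            raw.sort(key=lambda item: int(item[1]))
        else:
            raw.sort(key=lambda item: item[0][0], reverse=info["strand"] == "-")
        exon_objs = tuple(
            Exon(start=iv[0], end=iv[1], rank=i + 1) for i, (iv, _) in enumerate(raw)
        )
        model = TranscriptModel(
            gene_id=info["gene_id"],
            gene_name=info["gene_name"],
            transcript_id=tid,
            contig=info["contig"],
            strand=info["strand"],
            exons=exon_objs,
        )
        if tid in cds:
            offsets = []
            for start, end in cds[tid]:
                offsets.append(model.genomic_to_transcript(start))
                offsets.append(model.genomic_to_transcript(end - 1))
            cds_start, cds_end = min(offsets), max(offsets) + 1
            model = replace(model, cds_start=cds_start, cds_end=cds_end)
        models.append(model)
    return models


def write_annotation(
    models: Iterable[TranscriptModel],
    path: str | os.PathLike,
    header_comment: Optional[str] = None,
) -> None:
    """Write models as an Ensembl-dialect GTF (exon + CDS + stop_codon rows).

    The final 3 nt of a coding span are emitted as ``stop_codon`` so that a
    read/write round trip reproduces the models field-for-field.
    """

    def fmt(model, feature, start, end, extra=""):
        attrs = (
            f'gene_id "{model.gene_id}"; transcript_id "{model.transcript_id}"; '
            f'gene_name "{model.gene_name}";{extra}'
        )
        return (
            f"{model.contig}\tfusiontriage\t{feature}\t{start + 1}\t{end}\t.\t"
            f"{model.strand}\t.\t{attrs}\n"
        )

    lines = []
    if header_comment:
        lines.append(f"#{header_comment}\n")
    for model in models:
        for ex in model.exons:
            lines.append(
                fmt(model, "exon", ex.start, ex.end, f' exon_number "{ex.rank}";')
            )
        if model.is_coding:
            spans = {
                "CDS": (model.cds_start, max(model.cds_start, model.cds_end - 3)),
                "stop_codon": (max(model.cds_start, model.cds_end - 3), model.cds_end),
            }
            for feature, (t_start, t_end) in spans.items():
                if t_end <= t_start:
                    continue
                for g_start, g_end in _transcript_span_to_genomic(
                    model, t_start, t_end
                ):
                    lines.append(fmt(model, feature, g_start, g_end))
    with open(path, "w") as fh:
        fh.writelines(lines)


def _transcript_span_to_genomic(
    model: TranscriptModel, t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Decompose a transcript-coordinate span into genomic half-open blocks."""
    blocks = []
    cum = 0
    for ex in model.exons:
        lo = max(t_start, cum)
        hi = min(t_end, cum + len(ex))
        if lo < hi:
            if model.strand == "+":
                blocks.append((ex.start + (lo - cum), ex.start + (hi - cum)))
            else:
                blocks.append((ex.end - (hi - cum), ex.end - (lo - cum)))
        cum += len(ex)
    return sorted(blocks)


# ---------------------------------------------------------------------------
# Domain table / gene list
# ---------------------------------------------------------------------------

DOMAIN_COLUMNS = ("gene", "domain", "start_res", "end_res")


def read_domain_table(path: str | os.PathLike) -> list[DomainAnnotation]:
    """Read a TSV with header ``gene domain start_res end_res``.

    Unknown columns are ignored; rows with ``start_res > end_res`` are
    rejected with a logged message.
    """
    import pandas as pd

    try:
        table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise InputFormatError(f"cannot parse domain table {path}: {exc}") from exc
    missing = [c for c in DOMAIN_COLUMNS if c not in table.columns]
    if missing:
        raise InputFormatError(
            f"domain table {path} missing columns {missing}; header must contain "
            f"{DOMAIN_COLUMNS}"
        )
    records = []
    for _, row in table.iterrows():
        try:
            records.append(
                DomainAnnotation(
                    gene_name=str(row["gene"]).upper(),
                    domain_name=str(row["domain"]),
                    start_residue=int(row["start_res"]),
                    end_residue=int(row["end_res"]),
                )
            )
        except (ValueError, InputFormatError) as exc:
            logger.warning("domain row rejected (%s): %s", exc, row.to_dict())
    return records


def read_gene_list(path: str | os.PathLike) -> DruggableGeneList:
    """Read a gene list: one gene per line, optionally ``gene<TAB>note``."""
    genes = set()
    notes = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene\t"):
                continue
            parts = line.split("\t")
            name = parts[0].strip().upper()
            if not name:
                continue
            genes.add(name)
            if len(parts) > 1 and parts[1].strip():
                notes[name] = parts[1].strip()
    return DruggableGeneList(genes=frozenset(genes), notes=notes)


def select_transcript(
    models: Sequence[TranscriptModel],
    gene_name: str,
    transcript_id: Optional[str] = None,
) -> TranscriptModel:
    """Pick the transcript for a gene: the caller-named one when present,
    otherwise the one with the longest CDS (ties broken by transcript_id)."""
    candidates = [
        m
        for m in models
        if m.gene_name.upper() == gene_name.upper() or m.gene_id == gene_name
    ]
    if not candidates:
        raise AnnotationError(f"gene {gene_name!r} absent from annotation")
    if transcript_id is not None:
        for m in candidates:
            if m.transcript_id == transcript_id:
                return m
        logger.warning(
            "transcript %s not found for gene %s; falling back to longest CDS",
            transcript_id,
            gene_name,
        )
    coding = [m for m in candidates if m.is_coding]
    pool = coding or candidates
    return max(pool, key=lambda m: ((m.cds_length or 0), m.length, m.transcript_id))
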