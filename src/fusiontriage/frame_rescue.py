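"""Chimeric transcript reconstruction, junction reading-frame classification
and scanning for downstream translation starts that restore the 3' partner's
native open reading frame.

Labeling rule: ATG1 is the 5' partner's annotated start codon; ATG2, ATG3,
... are successive frame-restoring ATGs downstream of the junction in
transcript order.  Non-restoring downstream ATGs are reported but carry no
label.  Every ATG is a candidate start; no initiation-context scoring is
applied.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .errors import AnnotationError, CoordinateError
from .fusion_calls import (
    FIVE_PRIME,
    IN_FRAME,
    OUT_OF_FRAME,
    UNKNOWN,
    Breakpoint,
    HarmonizedFusion,
)
from .reference_io import (
    DomainAnnotation,
    GenomeSequence,
    TranscriptModel,
    select_transcript,
    spliced_sequence,
)

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class FusionTranscript:
    """A reconstructed chimeric cDNA with coordinate maps to both partners.

    ``sequence[:junction_offset]`` comes from the 5' partner transcript
    interval ``[0, cut5)``; ``sequence[junction_offset:]`` from the 3'
    partner interval ``[cut3, length)``.
    """

    sequence: str
    junction_offset: int
    five_model: TranscriptModel
    three_model: TranscriptModel
    cut5: int  # transcript coordinate one past the last retained 5' base
    cut3: int  # transcript coordinate of the first retained 3' base
    cds_start_5p: Optional[int]  # offset of ATG1 in the fusion, if retained
    cds_start_3p: int  # 3' partner CDS start in its own transcript coords
    cds_end_3p: int  # 3' partner CDS end (incl. stop) in its own coords

    def __post_init__(self):
        if not 0 < self.junction_offset < len(self.sequence):
            raise AnnotationError(
                f"junction offset {self.junction_offset} not inside sequence"
            )

    # -- coordinate maps ---------------------------------------------------

    def map_5p(self, offset: int) -> int:
        """Fusion offset -> wild-type 5' transcript coordinate."""
        if not 0 <= offset < self.junction_offset:
            raise CoordinateError(f"offset {offset} not in the 5' portion")
        return offset

    def map_3p(self, offset: int) -> int:
        """Fusion offset -> wild-type 3' transcript coordinate."""
        if not self.junction_offset <= offset < len(self.sequence):
            raise CoordinateError(f"offset {offset} not in the 3' portion")
        return offset - self.junction_offset + self.cut3

    @property
    def native_phase_3p(self) -> Optional[int]:
        """Position within its native codon of the first retained 3' base
        (0 = codon start); None when the junction lies in the 3' 5'UTR."""
        if self.cut3 < self.cds_start_3p:
            return None
        return (self.cut3 - self.cds_start_3p) % 3

    @property
    def three_prime_protein_offset(self) -> Optional[int]:
        """1-based residue of the first fully retained native 3' codon."""
        phase = self.native_phase_3p
        if phase is None:
            return 1 if self.cds_start_3p >= self.cut3 else None
        first_full = self.cut3 + ((3 - phase) % 3)
        return (first_full - self.cds_start_3p) // 3 + 1

    @property
    def three_exon_rank(self) -> int:
        """Exon rank of the 3' partner at which the fusion sequence begins."""
        return self.three_model.exon_rank_at_offset(self.cut3)

    @property
    def annotated_stop_offset(self) -> Optional[int]:
        """Fusion offset of the 3' partner's annotated stop codon start."""
        stop_start = self.cds_end_3p - 3
        if stop_start < self.cut3:
            return None
        return stop_start - self.cut3 + self.junction_offset


@dataclass(frozen=True)
class FrameVerdict:
    status: str  # in_frame | out_of_frame | indeterminate
    stop_distance_codons: Optional[int] = None


@dataclass(frozen=True)
class OrfPrediction:
    start_offset: int
    start_label: Optional[str]  # ATG1/ATG2/... or None for unlabeled starts
    frame_restoring: bool
    stop_offset: Optional[int]  # None = runs to the annotated 3' stop
    protein_length_aa: int
    wildtype_start_residue: Optional[int]
    kinase_domain_covered: bool


def _native_offset_of(ft: FusionTranscript, offset: int) -> Optional[int]:
    """3' partner transcript coordinate for a fusion offset, or None."""
    if offset < ft.junction_offset:
        return None
    return ft.map_3p(offset)


def _is_frame_restoring(ft: FusionTranscript, offset: int) -> bool:
    native = _native_offset_of(ft, offset)
    if native is None or native < ft.cds_start_3p:
        return False
    if native >= ft.cds_end_3p - 3:  # at/past the stop codon: no residue exists
        return False
    return (native - ft.cds_start_3p) % 3 == 0


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _resolve_cut(
    model: TranscriptModel, bp: Breakpoint, genome_is_toy: bool = False
) -> int:
    """Transcript-coordinate cut for a breakpoint.

    Returns ``cut5`` (one past last retained base) for five_prime
    breakpoints and ``cut3`` (first retained base) for three_prime ones.
    Exon-rank annotations take precedence; genomic positions must be exonic.
    """
    if bp.exon_rank is not None:
        span = model.exon_transcript_span(bp.exon_rank)
        return span[1] if bp.retained_side == FIVE_PRIME else span[0]
    try:
        offset = model.genomic_to_transcript(bp.position)
    except CoordinateError as exc:
        raise CoordinateError(
            f"breakpoint {bp.contig}:{bp.position + 1} of {bp.gene_name} is not "
            f"exonic in {model.transcript_id} and cannot be snapped: {exc}"
        ) from exc
    return offset + 1 if bp.retained_side == FIVE_PRIME else offset


def build_fusion_transcript(
    fusion: HarmonizedFusion,
    models: Sequence[TranscriptModel],
    genome: GenomeSequence,
) -> FusionTranscript:
    """Reconstruct the chimeric cDNA for a harmonized fusion.

    The 5' partner contributes its spliced sequence through the breakpoint,
    the 3' partner from the breakpoint on.  A breakpoint at an annotated exon
    boundary retains the full exon on the retained side.
    """
    bp5, bp3 = fusion.five_prime, fusion.three_prime
    model5 = select_transcript(models, bp5.gene_name, bp5.transcript_id)
    model3 = select_transcript(models, bp3.gene_name, bp3.transcript_id)
    if not model3.is_coding:
        raise AnnotationError(
            f"3' partner transcript {model3.transcript_id} is non-coding; frame "
            "analysis undefined"
        )
    seq5 = spliced_sequence(model5, genome)
    seq3 = spliced_sequence(model3, genome)
    cut5 = _resolve_cut(model5, bp5)
    cut3 = _resolve_cut(model3, bp3)
    if not 0 < cut5 <= len(seq5):
        raise CoordinateError(f"5' cut {cut5} outside transcript {model5.transcript_id}")
    if not 0 <= cut3 < len(seq3):
        raise CoordinateError(f"3' cut {cut3} outside transcript {model3.transcript_id}")
    cds_start_5p = (
        model5.cds_start
        if model5.is_coding and model5.cds_start is not None and model5.cds_start < cut5
        else None
    )
    return FusionTranscript(
        sequence=seq5[:cut5] + seq3[cut3:],
        junction_offset=cut5,
        five_model=model5,
        three_model=model3,
        cut5=cut5,
        cut3=cut3,
        cds_start_5p=cds_start_5p,
        cds_start_3p=model3.cds_start,
        cds_end_3p=model3.cds_end,
    )


def build_from_cdna(
    cdna: str,
    model5: TranscriptModel,
    model3: TranscriptModel,
    genome: GenomeSequence,
) -> FusionTranscript:
    """Locate the junction of a fusion cDNA by matching its prefix to the 5'
    partner transcript and its suffix to the 3' partner transcript."""
    cdna = cdna.upper().replace("\n", "")
    if not model3.is_coding:
        raise AnnotationError("3' partner transcript is non-coding")
    seq5 = spliced_sequence(model5, genome)
    seq3 = spliced_sequence(model3, genome)
    lcp = 0
    while lcp < min(len(cdna), len(seq5)) and cdna[lcp] == seq5[lcp]:
        lcp += 1
    lcs = 0
    while (
        lcs < min(len(cdna), len(seq3))
        and cdna[len(cdna) - 1 - lcs] == seq3[len(seq3) - 1 - lcs]
    ):
        lcs += 1
    lo = len(cdna) - lcs  # smallest admissible junction offset
    if lo > lcp or lcp <= 0 or lo >= len(cdna):
        raise AnnotationError(
            "fusion cDNA does not decompose into a 5' partner prefix and a 3' "
            f"partner suffix (prefix match {lcp} nt, suffix match {lcs} nt)"
        )
    # Junction microhomology makes any offset in [lo, lcp] consistent with
    # the decomposition; prefer one where the 3' cut lands on an annotated
    # exon boundary (exon-level fusions), then one where the 5' cut does,
    # falling back to maximal 3' retention.
    hi = min(lcp, len(cdna) - 1)
    exon3_starts = {model3.exon_transcript_span(r)[0] for r in range(1, model3.n_exons + 1)}
    exon5_ends = {model5.exon_transcript_span(r)[1] for r in range(1, model5.n_exons + 1)}
    junction = lo
    for j in range(lo, hi + 1):
        if len(seq3) - (len(cdna) - j) in exon3_starts:
            junction = j
            break
    else:
        for j in range(lo, hi + 1):
            if j in exon5_ends:
                junction = j
                break
    cut3 = len(seq3) - (len(cdna) - junction)
    if not 0 < junction < len(cdna) or not 0 <= cut3 < len(seq3):
        raise AnnotationError(
            f"inferred junction offset {junction} is degenerate for this cDNA"
        )
    cds_start_5p = (
        model5.cds_start
        if model5.is_coding and model5.cds_start is not None
        and model5.cds_start < junction
        else None
    )
    return FusionTranscript(
        sequence=cdna,
        junction_offset=junction,
        five_model=model5,
        three_model=model3,
        cut5=junction,
        cut3=cut3,
        cds_start_5p=cds_start_5p,
        cds_start_3p=model3.cds_start,
        cds_end_3p=model3.cds_end,
    )


# ---------------------------------------------------------------------------
# Frame classification
# ---------------------------------------------------------------------------

def _first_stop_from(sequence: str, start: int) -> Optional[int]:
    """Offset of the first stop codon reading codons from ``start``."""
    for pos in range(start, len(sequence) - 2, 3):
        if sequence[pos : pos + 3] in STOP_CODONS:
            return pos
    return None


def classify_frame(ft: FusionTranscript) -> FrameVerdict:
    """Classify the junction reading frame by translating from ATG1.

    in_frame requires both the codon-phase match between partners and an
    uninterrupted reading through to the 3' partner's annotated stop.
    ``stop_distance_codons`` counts complete codons starting at or after the
    junction, up to and including the first stop met from ATG1.
    """
    if ft.cds_start_5p is None:
        return FrameVerdict(status=INDETERMINATE)
    phase3 = ft.native_phase_3p
    stop = _first_stop_from(ft.sequence, ft.cds_start_5p)
    stop_distance = None
    if stop is not None and stop >= ft.junction_offset:
        stop_distance = (stop - ft.junction_offset) // 3 + 1
    elif stop is not None:
        stop_distance = 0  # stop before or straddling the junction

    if phase3 is not None and (ft.junction_offset - ft.cds_start_5p) % 3 == phase3:
        annotated = ft.annotated_stop_offset
        if stop is not None and annotated is not None and stop == annotated:
            return FrameVerdict(status=IN_FRAME, stop_distance_codons=None)
        # phase matches but translation is interrupted (e.g. junction codon
        # forms a stop) or the annotated stop is lost
        return FrameVerdict(status=OUT_OF_FRAME, stop_distance_codons=stop_distance)
    return FrameVerdict(status=OUT_OF_FRAME, stop_distance_codons=stop_distance)


# ---------------------------------------------------------------------------
# Downstream start scanning
# ---------------------------------------------------------------------------

def map_offset_to_residue(ft: FusionTranscript, offset: int) -> int:
    """1-based wild-type 3' protein residue of the codon starting at
    ``offset``; the offset must lie on the native 3' codon grid."""
    native = _native_offset_of(ft, offset)
    if native is None:
        raise CoordinateError(f"offset {offset} is upstream of the junction")
    if native < ft.cds_start_3p or (native - ft.cds_start_3p) % 3 != 0:
        raise CoordinateError(
            f"offset {offset} (native {native}) is off the native codon grid"
        )
    return (native - ft.cds_start_3p) // 3 + 1


def _domain_coverage(
    residue: int,
    stop_residue: Optional[int],
    domains: Sequence[DomainAnnotation],
    gene_name: str,
    partial: bool = False,
) -> bool:
    """Does an ORF starting at wild-type ``residue`` (running to
    ``stop_residue``, None = native end) cover a domain of ``gene_name``?"""
    for dom in domains:
        if dom.gene_name.upper() != gene_name.upper():
            continue
        start_ok = residue <= (dom.end_residue if partial else dom.start_residue)
        end_ok = stop_residue is None or stop_residue >= dom.end_residue
        if start_ok and end_ok:
            return True
    return False


def scan_downstream_starts(
    ft: FusionTranscript,
    domains: Sequence[DomainAnnotation] = (),
    max_starts: int = 10,
    partial_domain: bool = False,
) -> list[OrfPrediction]:
    """Enumerate candidate translation starts of the fusion transcript.

    The first entry (when ATG1 is retained) describes translation from the 5'
    partner's start codon.  Every ATG at or downstream of the junction is then
    reported in transcript order; frame-restoring ones are labeled ATG2, ATG3,
    ... and mapped to wild-type 3' protein residues.  The list is truncated
    after ``max_starts`` frame-restoring entries (non-restoring entries up to
    the same offset are kept).
    """
    if max_starts < 1:
        raise ValueError("max_starts must be >= 1")
    seq = ft.sequence
    predictions: list[OrfPrediction] = []

    if ft.cds_start_5p is not None:
        verdict = classify_frame(ft)
        stop = _first_stop_from(seq, ft.cds_start_5p)
        runs_to_annotated = (
            verdict.status == IN_FRAME
        )  # in_frame implies the annotated stop is reached
        protein_len = (
            (stop - ft.cds_start_5p) // 3
            if stop is not None
            else (len(seq) - ft.cds_start_5p) // 3
        )
        predictions.append(
            OrfPrediction(
                start_offset=ft.cds_start_5p,
                start_label="ATG1",
                frame_restoring=runs_to_annotated,
                stop_offset=None if runs_to_annotated else stop,
                protein_length_aa=protein_len,
                wildtype_start_residue=None,
                kinase_domain_covered=(
                    runs_to_annotated
                    and _domain_coverage(
                        max(ft.three_prime_protein_offset or 1, 1),
                        None,
                        domains,
                        ft.three_model.gene_name,
                        partial_domain,
                    )
                ),
            )
        )

    n_restoring = 0
    label_index = 2
    annotated_stop = ft.annotated_stop_offset
    for pos in range(ft.junction_offset, len(seq) - 2):
        if seq[pos : pos + 3] != "ATG":
            continue
        restoring = _is_frame_restoring(ft, pos)
        stop = _first_stop_from(seq, pos)
        residue = None
        label = None
        covered = False
        stop_offset: Optional[int] = stop
        if restoring:
            residue = map_offset_to_residue(ft, pos)
            if stop is not None and stop == annotated_stop:
                stop_offset = None  # runs to the annotated 3' stop
            label = f"ATG{label_index}"
            label_index += 1
            n_restoring += 1
            stop_residue = (
                None if stop_offset is None else map_offset_to_residue(ft, stop)
            )
            covered = _domain_coverage(
                residue, stop_residue, domains, ft.three_model.gene_name, partial_domain
            )
        protein_len = (
            (stop - pos) // 3 if stop is not None else (len(seq) - pos) // 3
        )
        predictions.append(
            OrfPrediction(
                start_offset=pos,
                start_label=label,
                frame_restoring=restoring,
                stop_offset=stop_offset,
                protein_length_aa=protein_len,
                wildtype_start_residue=residue,
                kinase_domain_covered=covered,
            )
        )
        if n_restoring >= max_starts:
            break
    return predictions


def translate_prediction(ft: FusionTranscript, pred: OrfPrediction) -> str:
    """Amino-acid sequence of a predicted ORF (stop codon excluded)."""
    end = pred.stop_offset
    if end is None:
        end = ft.annotated_stop_offset if pred.frame_restoring else None
    if end is None:
        end = pred.start_offset + 3 * pred.protein_length_aa
    sub = ft.sequence[pred.start_offset : end]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate())


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_orf_fasta(
    ft: FusionTranscript,
    predictions: Sequence[OrfPrediction],
    path: str | os.PathLike,
    peptide: bool = False,
) -> None:
    """Write predicted ORFs as FASTA; headers carry label, wild-type residue
    and domain-coverage status."""
    name = f"{ft.five_model.gene_name}::{ft.three_model.gene_name}"
    with open(path, "w") as fh:
        for i, pred in enumerate(predictions):
            label = pred.start_label or f"start_{pred.start_offset}"
            header = (
                f">{name}|{label}|offset={pred.start_offset}"
                f"|frame_restoring={pred.frame_restoring}"
                f"|wildtype_start_residue={pred.wildtype_start_residue}"
                f"|kinase_domain_covered={pred.kinase_domain_covered}"
            )
            if peptide:
                seq = translate_prediction(ft, pred)
            else:
                end = (
                    pred.stop_offset + 3
                    if pred.stop_offset is not None
                    else len(ft.sequence)
                )
                seq = ft.sequence[pred.start_offset : end]
            fh.write(header + "\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j : j + 60] + "\n")


def frame_report(
    ft: FusionTranscript,
    verdict: FrameVerdict,
    predictions: Sequence[OrfPrediction],
) -> dict:
    """JSON-serializable report of a frame/rescue analysis."""
    return {
        "fusion": f"{ft.five_model.gene_name}::{ft.three_model.gene_name}",
        "five_transcript": ft.five_model.transcript_id,
        "three_transcript": ft.three_model.transcript_id,
        "junction_offset": ft.junction_offset,
        "three_exon_rank": ft.three_exon_rank,
        "native_phase_3p": ft.native_phase_3p,
        "three_prime_protein_offset": ft.three_prime_protein_offset,
        "frame_verdict": asdict(verdict),
        "orf_predictions": [asdict(p) for p in predictions],
    }


def write_frame_report(report: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
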