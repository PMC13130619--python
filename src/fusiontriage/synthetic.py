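"""Self-contained toy references, engineered fusion events and exon-count
tables with the statistical structure the analysis assumes.

The generator co-designs the two partner genes around the requested fusion:
exon boundaries are placed so the breakpoints fall exactly at them, the 5'
UTR length of the 5' partner sets the junction frame shift, a premature stop
is planted in the translated-from-ATG1 frame a configurable number of codons
past the junction, and frame-restoring ATGs are planted at requested
wild-type residues of the 3' partner without altering the downstream
protein (the planted features are part of the reference itself).

All randomness flows from a single seed; every output file embeds the seed
in a header comment (FASTA records carry it in their description).
"""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .fusion_calls import (
    FIVE_PRIME,
    IN_FRAME,
    OUT_OF_FRAME,
    THREE_PRIME,
    Breakpoint,
    FusionCall,
)
from .reference_io import (
    DomainAnnotation,
    Exon,
    GenomeSequence,
    TranscriptModel,
    write_annotation,
)

logger = logging.getLogger(__name__)

STOPS = ("TAA", "TAG", "TGA")
BASES = "ACGT"
#: sense codons excluding ATG, so planted ATGs are the only native-frame
#: methionines downstream of the start codon
CODON_POOL = tuple(
    "".join(c)
    for c in itertools.product(BASES, repeat=3)
    if "".join(c) not in STOPS and "".join(c) != "ATG"
)


@dataclass(frozen=True)
class GeneSpec:
    name: str
    n_exons: int = 7
    cds_codons: int = 120  # residues incl. start Met, excl. stop
    strand: str = "+"
    min_exon_nt: int = 6

    def __post_init__(self):
        if self.n_exons < 1 or self.cds_codons < 10:
            raise ConfigError(f"infeasible gene spec for {self.name}")


@dataclass(frozen=True)
class FusionSpec:
    five_exon: int = 2  # last retained exon of the 5' partner
    three_exon: int = 18  # first retained exon of the 3' partner
    frame_shift: int = 1  # 0 | 1 | 2; 0 = in-frame
    rescue_residues: tuple[int, ...] = (250, 274)
    premature_stop_codons: int = 2  # stop planted this many codons past junction
    five_cut_codon: int = 60  # native codon index of the 5' cut (0-based)
    three_cut_codon: int = 240  # native codon index at which three_exon begins
    three_cut_phase: int = 0  # 0|1|2 within-codon position of the 3' cut
    in_strand: bool = True
    caller_frame_label: Optional[str] = None  # None -> label with the truth

    def __post_init__(self):
        if self.frame_shift not in (0, 1, 2):
            raise ConfigError("frame_shift must be 0, 1 or 2")
        if self.three_cut_phase not in (0, 1, 2):
            raise ConfigError("three_cut_phase must be 0, 1 or 2")
        if self.premature_stop_codons < 1:
            raise ConfigError("premature_stop_codons must be >= 1")


@dataclass(frozen=True)
class CountSpec:
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    fold_change: float = 10.0

    def __post_init__(self):
        if self.fold_change <= 0 or self.dispersion < 0 or self.baseline_mean <= 0:
            raise ConfigError("invalid count model parameters")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    five_gene: GeneSpec = field(default_factory=lambda: GeneSpec(name="GENEA"))
    three_gene: GeneSpec = field(
        default_factory=lambda: GeneSpec(name="KINB", n_exons=29, cds_codons=360)
    )
    fusion: FusionSpec = field(default_factory=FusionSpec)
    counts: CountSpec = field(default_factory=CountSpec)
    domain_start_residue: int = 290
    domain_end_residue: int = 345
    domain_name: str = "Protein kinase"
    contig_prefix: str = "chr"


@dataclass
class ToyReference:
    genome: GenomeSequence
    models: list[TranscriptModel]
    domains: list[DomainAnnotation]
    gene_names: list[str]
    config: SimulationConfig
    # transcript-coordinate cut points implied by the fusion spec
    cut5: int = 0
    cut3: int = 0

    def model_of(self, gene_name: str) -> TranscriptModel:
        for m in self.models:
            if m.gene_name == gene_name:
                return m
        raise ConfigError(f"gene {gene_name} not in toy reference")


@dataclass(frozen=True)
class GroundTruth:
    fusion_id: str
    frame_status: str
    stop_distance_codons: Optional[int]
    rescue_residues: tuple[int, ...]
    junction_offset: int
    five_exon: int
    three_exon: int
    three_prime_protein_offset: int
    in_strand: bool


@dataclass
class EngineeredFusion:
    calls: list[FusionCall]  # one per emulated caller dialect
    truth: GroundTruth
    cdna: str
    reference: ToyReference


# ---------------------------------------------------------------------------
# Sequence construction helpers
# ---------------------------------------------------------------------------

def _random_utr(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(BASES), size=length))


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    """Start codon + random sense non-ATG codons + TAA stop, as a base list."""
    codons = ["ATG"] + [
        CODON_POOL[i] for i in rng.integers(0, len(CODON_POOL), size=n_codons - 1)
    ] + ["TAA"]
    return list("".join(codons))


def _partition(
    rng: np.random.Generator, total: int, parts: int, minimum: int
) -> list[int]:
    """Random composition of ``total`` into ``parts`` parts each >= minimum."""
    if parts * minimum > total:
        raise ConfigError(
            f"cannot split {total} nt into {parts} exons of >= {minimum} nt"
        )
    extra = rng.multinomial(total - parts * minimum, np.ones(parts) / parts)
    return [minimum + int(e) for e in extra]


def _is_stop(codon: str) -> bool:
    return codon in STOPS


class _GeneDraft:
    """Mutable transcript sequence of one toy gene during co-design."""

    def __init__(self, spec: GeneSpec, rng: np.random.Generator):
        self.spec = spec
        self.utr5 = 15 + int(rng.integers(0, 10))
        self.bases = (
            _random_utr(rng, self.utr5)
            + _random_cds(rng, spec.cds_codons)
            + _random_utr(rng, 15 + int(rng.integers(0, 10)))
        )
        self.cds_start = self.utr5
        self.cds_end = self.utr5 + 3 * (spec.cds_codons + 1)  # incl. stop codon

    def codon(self, index: int) -> str:
        s = self.cds_start + 3 * index
        return "".join(self.bases[s : s + 3])

    def set_codon(self, index: int, codon: str) -> None:
        s = self.cds_start + 3 * index
        self.bases[s : s + 3] = list(codon)

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def sequence(self) -> str:
        return "".join(self.bases)


def _sanitize_fusion_frame(
    g5: _GeneDraft,
    g3: _GeneDraft,
    cut5: int,
    cut3: int,
    spec: FusionSpec,
    rng: np.random.Generator,
) -> None:
    """Mutate the drafts so that translation from ATG1 through the fusion
    junction behaves exactly as requested.

    For ``frame_shift == 0`` the only hazard is a junction-straddling stop
    codon.  Otherwise the translated frame is off the 3' partner's codon
    grid: all stops before the planted one are cleared and a TAA is planted
    ``premature_stop_codons`` codons past the junction.
    """
    protected = {0} | {r - 1 for r in spec.rescue_residues}

    def fusion_seq() -> str:
        return g5.sequence[:cut5] + g3.sequence[cut3:]

    junction = cut5
    # fusion offset of the stop target in the ATG1 frame (frame-shifted case)
    first_codon = junction + (-(junction - g5.cds_start)) % 3
    target = first_codon + 3 * (spec.premature_stop_codons - 1)
    native_target = target - junction + cut3

    if spec.frame_shift != 0 and native_target + 3 > g3.cds_end - 3:
        raise ConfigError(
            "premature stop would fall at or past the 3' partner stop codon"
        )
    for r in spec.rescue_residues:
        s = g3.cds_start + 3 * (r - 1)
        if spec.frame_shift != 0 and not (s + 3 <= native_target or s >= native_target + 3):
            raise ConfigError(f"rescue residue {r} collides with the planted stop")

    def overlapped_g3_codons(native_pos: int) -> list[int]:
        lo = (native_pos - g3.cds_start) // 3
        hi = (native_pos + 2 - g3.cds_start) // 3
        return [i for i in range(lo, hi + 1) if 0 <= i <= g3.spec.cds_codons]

    def resample_g3(indices: Sequence[int], keep: dict[int, str]) -> bool:
        """Resample one non-protected overlapped codon; keep planted bases."""
        for idx in indices:
            if idx in protected or idx == g3.spec.cds_codons:
                continue
            start = g3.cds_start + 3 * idx
            for _ in range(50):
                codon = CODON_POOL[int(rng.integers(0, len(CODON_POOL)))]
                merged = "".join(
                    keep.get(start + k, codon[k]) for k in range(3)
                )
                if not _is_stop(merged) and merged != "ATG":
                    g3.set_codon(idx, merged)
                    return True
        return False

    planted: dict[int, str] = {}

    if spec.frame_shift != 0:
        # plant the stop, fixing any overlapped native codon it disturbs
        for k, base in enumerate("TAA"):
            g3.bases[native_target + k] = base
            planted[native_target + k] = base
        for idx in overlapped_g3_codons(native_target):
            codon = g3.codon(idx)
            if (_is_stop(codon) and g3.cds_start + 3 * idx != native_target) or (
                codon == "ATG" and idx not in protected
            ):
                if not resample_g3([idx], planted):
                    raise ConfigError("cannot sanitize codons around planted stop")

    for _ in range(1000):
        seq = fusion_seq()
        offender = None
        for pos in range(g5.cds_start, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if not _is_stop(codon):
                continue
            if spec.frame_shift == 0:
                annotated = g3.cds_end - 3 - cut3 + junction
                if pos == annotated:
                    break  # reached the native stop: clean
                offender = pos
                break
            if pos == target:
                break  # first stop is the planted one: done
            offender = pos
            break
        if offender is None:
            return
        if offender < junction:
            # inside (or straddling from) the 5' partner CDS
            idx5 = (offender - g5.cds_start) // 3
            if idx5 <= 0 or idx5 >= g5.spec.cds_codons:
                raise ConfigError("stop codon at an unexpected 5' position")
            g5.set_codon(idx5, CODON_POOL[int(rng.integers(0, len(CODON_POOL)))])
        else:
            native_pos = offender - junction + cut3
            if not resample_g3(overlapped_g3_codons(native_pos), planted):
                raise ConfigError(
                    "cannot clear a premature stop overlapping protected codons"
                )
    raise ConfigError("failed to sanitize fusion reading frame (unlucky config)")


def _lay_out_gene(
    draft: _GeneDraft,
    cut: Optional[int],
    exons_before: int,
    contig: str,
    gene_id: str,
    rng: np.random.Generator,
) -> tuple[str, TranscriptModel]:
    """Split a transcript into exons (cut at an exon boundary) and emit the
    genomic contig sequence plus the transcript model."""
    spec = draft.spec
    n = spec.n_exons
    length = draft.length
    if cut is None:
        lengths = _partition(rng, length, n, spec.min_exon_nt)
    else:
        if not 0 < cut < length:
            raise ConfigError(f"cut {cut} outside transcript of {spec.name}")
        lengths = _partition(rng, cut, exons_before, spec.min_exon_nt) + _partition(
            rng, length - cut, n - exons_before, spec.min_exon_nt
        )
    # transcript-order exon chunks
    chunks = []
    pos = 0
    for ln in lengths:
        chunks.append(draft.sequence[pos : pos + ln])
        pos += ln
    pad = "".join(_random_utr(rng, 30))
    introns = ["".join(_random_utr(rng, 20 + int(rng.integers(0, 40)))) for _ in range(n - 1)]

    from Bio.Seq import reverse_complement

    genomic_chunks = (
        chunks if spec.strand == "+" else [reverse_complement(c) for c in chunks[::-1]]
    )
    contig_seq = pad
    spans = []
    for i, chunk in enumerate(genomic_chunks):
        start = len(contig_seq)
        contig_seq += chunk
        spans.append((start, len(contig_seq)))
        if i < n - 1:
            contig_seq += introns[i]
    contig_seq += pad
    if spec.strand == "-":
        spans = spans[::-1]  # back to transcript (rank) order
    exons = tuple(Exon(start=s, end=e, rank=i + 1) for i, (s, e) in enumerate(spans))
    model = TranscriptModel(
        gene_id=gene_id,
        gene_name=spec.name,
        transcript_id=f"{gene_id}.t1",
        contig=contig,
        strand=spec.strand,
        exons=exons,
        cds_start=draft.cds_start,
        cds_end=draft.cds_end,
    )
    return contig_seq, model


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def make_toy_reference(
    config: SimulationConfig, out_dir: Optional[str | os.PathLike] = None
) -> ToyReference:
    """Build a two-gene toy reference engineered around ``config.fusion``.

    The 3' gene carries a kinase-domain annotation in its 3' half.  Neither
    CDS contains spurious in-frame stops, and the fusion implied by the spec
    has exactly the requested frame shift, premature stop and rescue starts.
    Writes FASTA/GTF/domain-table/gene-list files when ``out_dir`` is given.
    """
    rng = np.random.default_rng(config.seed)
    fus = config.fusion
    g3 = _GeneDraft(config.three_gene, rng)
    cut3 = g3.cds_start + 3 * fus.three_cut_codon + fus.three_cut_phase
    if not g3.cds_start <= cut3 < g3.cds_end - 3:
        raise ConfigError("3' cut falls outside the 3' partner CDS")
    first_retained_residue = (cut3 - g3.cds_start + 2) // 3 + 1
    for r in fus.rescue_residues:
        if not first_retained_residue <= r <= config.three_gene.cds_codons:
            raise ConfigError(
                f"requested rescue residue {r} outside retained 3' region "
                f"(first retained residue {first_retained_residue})"
            )
        g3.set_codon(r - 1, "ATG")

    g5 = _GeneDraft(config.five_gene, rng)
    d5 = (fus.three_cut_phase + fus.frame_shift) % 3
    cut5 = g5.cds_start + 3 * fus.five_cut_codon + d5
    if not g5.cds_start + 3 <= cut5 <= g5.cds_end - 3:
        raise ConfigError("5' cut falls outside the 5' partner CDS")

    _sanitize_fusion_frame(g5, g3, cut5, cut3, fus, rng)

    contig5 = f"{config.contig_prefix}{config.five_gene.name}"
    contig3 = f"{config.contig_prefix}{config.three_gene.name}"
    seq5, model5 = _lay_out_gene(
        g5, cut5, fus.five_exon, contig5, f"G_{config.five_gene.name}", rng
    )
    seq3, model3 = _lay_out_gene(
        g3, cut3, fus.three_exon - 1, contig3, f"G_{config.three_gene.name}", rng
    )
    genome = GenomeSequence({contig5: seq5, contig3: seq3})
    domains = [
        DomainAnnotation(
            gene_name=config.three_gene.name,
            domain_name=config.domain_name,
            start_residue=config.domain_start_residue,
            end_residue=config.domain_end_residue,
        )
    ]
    ref = ToyReference(
        genome=genome,
        models=[model5, model3],
        domains=domains,
        gene_names=[config.five_gene.name, config.three_gene.name],
        config=config,
        cut5=cut5,
        cut3=cut3,
    )
    if out_dir is not None:
        write_reference(ref, out_dir)
    return ref


def write_reference(ref: ToyReference, out_dir: str | os.PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = ref.config.seed
    with open(out / "genome.fa", "w") as fh:
        for name in ref.genome.names:
            fh.write(f">{name} seed={seed}\n")
            seq = ref.genome.fetch(name, 0, ref.genome.length(name))
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    write_annotation(ref.models, out / "annotation.gtf", header_comment=f" seed={seed}")
    with open(out / "domains.tsv", "w") as fh:
        fh.write(f"# seed={seed}\n")
        fh.write("gene\tdomain\tstart_res\tend_res\n")
        for d in ref.domains:
            fh.write(
                f"{d.gene_name}\t{d.domain_name}\t{d.start_residue}\t{d.end_residue}\n"
            )
    with open(out / "gene_list.txt", "w") as fh:
        fh.write(f"# seed={seed}\n")
        for d in ref.domains:
            fh.write(d.gene_name + "\n")


def engineer_fusion(
    ref: ToyReference, out_dir: Optional[str | os.PathLike] = None
) -> EngineeredFusion:
    """Derive the engineered fusion event from a co-designed toy reference:
    emulated caller calls (all three dialects), the fusion cDNA, and the
    ground-truth frame/rescue record."""
    config = ref.config
    fus = config.fusion
    model5 = ref.model_of(config.five_gene.name)
    model3 = ref.model_of(config.three_gene.name)
    from .reference_io import spliced_sequence

    seq5 = spliced_sequence(model5, ref.genome)
    seq3 = spliced_sequence(model3, ref.genome)
    cut5, cut3 = ref.cut5, ref.cut3
    cdna = seq5[:cut5] + seq3[cut3:]

    status = IN_FRAME if fus.frame_shift == 0 else OUT_OF_FRAME
    stop_distance = None if fus.frame_shift == 0 else fus.premature_stop_codons
    phase3 = (cut3 - model3.cds_start) % 3
    first_full = cut3 + ((3 - phase3) % 3)
    truth = GroundTruth(
        fusion_id=f"{model5.gene_name}::{model3.gene_name}",
        frame_status=status,
        stop_distance_codons=stop_distance,
        rescue_residues=tuple(fus.rescue_residues),
        junction_offset=cut5,
        five_exon=fus.five_exon,
        three_exon=fus.three_exon,
        three_prime_protein_offset=(first_full - model3.cds_start) // 3 + 1,
        in_strand=fus.in_strand,
    )

    pos5 = model5.transcript_to_genomic(cut5 - 1)  # last retained base
    pos3 = model3.transcript_to_genomic(cut3)  # first retained base
    strand5 = model5.strand
    strand3 = model3.strand if fus.in_strand else ("-" if model3.strand == "+" else "+")
    frame_label = fus.caller_frame_label or status

    def bp(side: str, with_transcript: bool, with_exon: bool) -> Breakpoint:
        if side == FIVE_PRIME:
            return Breakpoint(
                contig=model5.contig,
                position=pos5,
                gene_name=model5.gene_name,
                strand=strand5,
                retained_side=FIVE_PRIME,
                transcript_id=model5.transcript_id if with_transcript else None,
                exon_rank=fus.five_exon if with_exon else None,
            )
        return Breakpoint(
            contig=model3.contig,
            position=pos3,
            gene_name=model3.gene_name,
            strand=strand3,
            retained_side=THREE_PRIME,
            transcript_id=model3.transcript_id if with_transcript else None,
            exon_rank=fus.three_exon if with_exon else None,
        )

    calls = [
        FusionCall(
            five_prime=bp(FIVE_PRIME, True, False),
            three_prime=bp(THREE_PRIME, True, False),
            caller_name="dialect_A",
            split_reads=2 + int(fus.five_exon),
            spanning_pairs=3,
            caller_frame_prediction=frame_label,
            caller_frame_raw=frame_label.replace("_", "-"),
        ),
        FusionCall(
            five_prime=bp(FIVE_PRIME, False, True),
            three_prime=bp(THREE_PRIME, False, True),
            caller_name="dialect_F",
            split_reads=3,
            spanning_pairs=4,
            caller_frame_prediction=frame_label,
            caller_frame_raw=frame_label.replace("_", "-"),
        ),
        FusionCall(
            five_prime=bp(FIVE_PRIME, False, False),
            three_prime=bp(THREE_PRIME, False, False),
            caller_name="dialect_S",
            split_reads=4,
            spanning_pairs=2,
        ),
    ]
    engineered = EngineeredFusion(calls=calls, truth=truth, cdna=cdna, reference=ref)
    if out_dir is not None:
        write_fusion_fixture(engineered, out_dir)
    return engineered


def write_fusion_fixture(fusion: EngineeredFusion, out_dir: str | os.PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = fusion.reference.config.seed
    with open(out / "fusion_cdna.fa", "w") as fh:
        fh.write(f">{fusion.truth.fusion_id} seed={seed}\n")
        for i in range(0, len(fusion.cdna), 60):
            fh.write(fusion.cdna[i : i + 60] + "\n")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({"seed": seed, **asdict(fusion.truth)}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_caller_tables([fusion], out)


def write_caller_tables(
    fusions: Sequence[EngineeredFusion], out_dir: str | os.PathLike
) -> None:
    """Write the engineered calls in all three caller dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows_a, rows_f, rows_s = [], [], []
    for ef in fusions:
        by_caller = {c.caller_name: c for c in ef.calls}
        a = by_caller["dialect_A"]
        rows_a.append(
            {
                "gene1": a.five_prime.gene_name,
                "gene2": a.three_prime.gene_name,
                "strand1(gene/fusion)": f"{a.five_prime.strand}/{a.five_prime.strand}",
                "strand2(gene/fusion)": f"{a.three_prime.strand}/{a.three_prime.strand}",
                "breakpoint1": f"{a.five_prime.contig}:{a.five_prime.position + 1}",
                "breakpoint2": f"{a.three_prime.contig}:{a.three_prime.position + 1}",
                "split_reads1": a.split_reads // 2,
                "split_reads2": a.split_reads - a.split_reads // 2,
                "discordant_mates": a.spanning_pairs,
                "reading_frame": a.caller_frame_raw or ".",
                "transcript_id1": a.five_prime.transcript_id or "",
                "transcript_id2": a.three_prime.transcript_id or "",
            }
        )
        f = by_caller["dialect_F"]
        rows_f.append(
            {
                "Gene_1_symbol(5end_fusion_partner)": f.five_prime.gene_name,
                "Gene_2_symbol(3end_fusion_partner)": f.three_prime.gene_name,
                "Exon_1_id(5end_fusion_partner)": (
                    f"{f.five_prime.gene_name}:exon{f.five_prime.exon_rank}"
                ),
                "Exon_2_id(3end_fusion_partner)": (
                    f"{f.three_prime.gene_name}:exon{f.three_prime.exon_rank}"
                ),
                "Fusion_point_for_gene_1(5end_fusion_partner)": (
                    f"{f.five_prime.contig}:{f.five_prime.position + 1}:"
                    f"{f.five_prime.strand}"
                ),
                "Fusion_point_for_gene_2(3end_fusion_partner)": (
                    f"{f.three_prime.contig}:{f.three_prime.position + 1}:"
                    f"{f.three_prime.strand}"
                ),
                "Spanning_pairs": f.spanning_pairs,
                "Spanning_unique_reads": f.split_reads,
                "Predicted_effect": f.caller_frame_raw or "unknown",
            }
        )
        s = by_caller["dialect_S"]
        rows_s.append(
            {
                "FusionName": f"{s.five_prime.gene_name}--{s.three_prime.gene_name}",
                "JunctionReadCount": s.split_reads,
                "SpanningFragCount": s.spanning_pairs,
                "LeftBreakpoint": (
                    f"{s.five_prime.contig}:{s.five_prime.position + 1}:"
                    f"{s.five_prime.strand}"
                ),
                "RightBreakpoint": (
                    f"{s.three_prime.contig}:{s.three_prime.position + 1}:"
                    f"{s.three_prime.strand}"
                ),
            }
        )
    pd.DataFrame(rows_a).to_csv(out / "calls_dialect_A.tsv", sep="\t", index=False)
    pd.DataFrame(rows_f).to_csv(out / "calls_dialect_F.tsv", sep="\t", index=False)
    pd.DataFrame(rows_s).to_csv(out / "calls_dialect_S.tsv", sep="\t", index=False)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    """Negative binomial with var = mean + dispersion * mean^2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_exon_counts(
    ref: ToyReference,
    rng: Optional[np.random.Generator] = None,
    count_spec: Optional[CountSpec] = None,
) -> pd.DataFrame:
    """Per-exon counts for both partners: negative-binomial with mean
    ``baseline_mean`` on non-retained exons and ``baseline_mean *
    fold_change`` on retained-side exons (5' partner: through the breakpoint
    exon; 3' partner: from it on)."""
    rng = rng if rng is not None else np.random.default_rng(ref.config.seed + 1)
    cs = count_spec or ref.config.counts
    fus = ref.config.fusion
    rows = []
    for gene, retained in (
        (ref.config.five_gene.name, lambda r: r <= fus.five_exon),
        (ref.config.three_gene.name, lambda r: r >= fus.three_exon),
    ):
        model = ref.model_of(gene)
        for ex in model.exons:
            mean = cs.baseline_mean * (cs.fold_change if retained(ex.rank) else 1.0)
            count = int(_nb_draw(rng, mean, cs.dispersion, 1)[0])
            rows.append(
                {
                    "gene": model.gene_name,
                    "transcript": model.transcript_id,
                    "contig": model.contig,
                    "start": ex.start + 1,
                    "end": ex.end,
                    "strand": model.strand,
                    "count": count,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The nine-fusion triage panel
# ---------------------------------------------------------------------------

PANEL_CASES = (
    # (case id, expected final class / note)
    ("fullpass", "candidate_functional_out_of_frame"),
    ("reclass", "in_frame_imbalanced_candidate"),
    ("failc1", "filtered"),
    ("failc2", "filtered"),
    ("failc4", "filtered"),
    ("failc5", "filtered"),
    ("norescue", "filtered"),
    ("needsinput", "filtered"),
    ("inframeflat", "filtered"),
)


def panel_configs(seed: int) -> dict[str, SimulationConfig]:
    """Deterministic per-case configs for the nine-fusion panel.

    One case per failure mode, one full pass and one reclassification case.
    The 5' partner gets 12 exons (breakpoint at exon 6) so its exact
    rank-sum test can reach significance.
    """
    configs = {}
    for i, (case, _) in enumerate(PANEL_CASES):
        five = GeneSpec(name=f"FIV{case.upper()}", n_exons=12)
        three = GeneSpec(name=f"KIN{case.upper()}", n_exons=29, cds_codons=360)
        fus = FusionSpec(five_exon=6, three_exon=18)
        domain = {"start": 290, "end": 345}
        if case == "reclass":
            fus = replace(
                fus,
                frame_shift=0,
                rescue_residues=(),
                caller_frame_label=OUT_OF_FRAME,
            )
        elif case == "failc2":
            fus = replace(fus, in_strand=False)
        elif case == "failc4":
            # domain begins upstream of the first retained residue (~241)
            domain = {"start": 200, "end": 260}
        elif case == "norescue":
            fus = replace(fus, rescue_residues=())
        elif case == "inframeflat":
            fus = replace(fus, frame_shift=0, rescue_residues=(), caller_frame_label=IN_FRAME)
        configs[case] = SimulationConfig(
            seed=seed + 1000 * i,
            five_gene=five,
            three_gene=three,
            fusion=fus,
            counts=CountSpec(
                fold_change=1.0 if case in ("failc5", "inframeflat") else 10.0
            ),
            domain_start_residue=domain["start"],
            domain_end_residue=domain["end"],
        )
    return configs


@dataclass
class Panel:
    fusions: dict[str, EngineeredFusion]
    counts: pd.DataFrame  # all cases except needsinput
    gene_list: list[str]  # kinase partners except failc1's
    expected: dict[str, str]  # case id -> expected final class
    seed: int

    @property
    def models(self) -> list[TranscriptModel]:
        return [m for ef in self.fusions.values() for m in ef.reference.models]

    @property
    def genome(self) -> GenomeSequence:
        merged = {}
        for ef in self.fusions.values():
            g = ef.reference.genome
            for name in g.names:
                merged[name] = g.fetch(name, 0, g.length(name))
        return GenomeSequence(merged)

    @property
    def domains(self) -> list[DomainAnnotation]:
        return [d for ef in self.fusions.values() for d in ef.reference.domains]


def make_panel(seed: int, out_dir: Optional[str | os.PathLike] = None) -> Panel:
    """Generate the nine-fusion synthetic panel (see :data:`PANEL_CASES`)."""
    configs = panel_configs(seed)
    fusions = {}
    count_frames = []
    gene_list = []
    for i, (case, expected) in enumerate(PANEL_CASES):
        config = configs[case]
        ref = make_toy_reference(config)
        fusions[case] = engineer_fusion(ref)
        if case != "failc1":
            gene_list.append(config.three_gene.name)
        if case != "needsinput":
            count_frames.append(
                simulate_exon_counts(ref, np.random.default_rng(seed + 1000 * i + 7))
            )
    counts = pd.concat(count_frames, ignore_index=True)
    panel = Panel(
        fusions=fusions,
        counts=counts,
        gene_list=gene_list,
        expected={case: exp for case, exp in PANEL_CASES},
        seed=seed,
    )
    if out_dir is not None:
        write_panel(panel, out_dir)
    return panel


def write_panel(panel: Panel, out_dir: str | os.PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = panel.seed
    genome = panel.genome
    with open(out / "genome.fa", "w") as fh:
        for name in sorted(genome.names):
            fh.write(f">{name} seed={seed}\n")
            seq = genome.fetch(name, 0, genome.length(name))
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    write_annotation(
        sorted(panel.models, key=lambda m: m.transcript_id),
        out / "annotation.gtf",
        header_comment=f" seed={seed}",
    )
    with open(out / "domains.tsv", "w") as fh:
        fh.write(f"# seed={seed}\n")
        fh.write("gene\tdomain\tstart_res\tend_res\n")
        for d in sorted(panel.domains, key=lambda d: d.gene_name):
            fh.write(
                f"{d.gene_name}\t{d.domain_name}\t{d.start_residue}\t{d.end_residue}\n"
            )
    with open(out / "gene_list.txt", "w") as fh:
        fh.write(f"# seed={seed}\n")
        for g in sorted(panel.gene_list):
            fh.write(g + "\n")
    from .imbalance import write_exon_counts

    write_exon_counts(panel.counts, out / "exon_counts.tsv", f" seed={seed}")
    write_caller_tables(
        [panel.fusions[case] for case, _ in PANEL_CASES], out
    )
    with open(out / "expected_classes.json", "w") as fh:
        payload = {
            panel.fusions[case].truth.fusion_id: exp for case, exp in PANEL_CASES
        }
        json.dump({"seed": seed, "expected": payload}, fh, indent=2, sort_keys=True)
        fh.write("\n")
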