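"""Fusion-caller table parsing (three dialects), breakpoint normalization,
cross-caller harmonization and the in-strand orientation check.

Dialects
--------
``dialect_A`` (Arriba-style TSV)::

    #gene1 gene2 strand1(gene/fusion) strand2(gene/fusion) breakpoint1
    breakpoint2 split_reads1 split_reads2 discordant_mates reading_frame

    breakpoints are "contig:position" (1-based); strands are "g/f" pairs,
    the fusion strand (after the slash) giving the transcribed orientation
    of the fragment.

``dialect_F`` (FusionCatcher-style TSV)::

    Gene_1_symbol(5end_fusion_partner) Gene_2_symbol(3end_fusion_partner)
    Exon_1_id(5end_fusion_partner) Exon_2_id(3end_fusion_partner)
    Fusion_point_for_gene_1(5end_fusion_partner)
    Fusion_point_for_gene_2(3end_fusion_partner)
    Spanning_pairs Spanning_unique_reads Predicted_effect

    fusion points are "contig:position:strand" (1-based).

``dialect_S`` (STAR-Fusion-style TSV)::

    #FusionName JunctionReadCount SpanningFragCount LeftBreakpoint
    RightBreakpoint

    FusionName is "GENE1--GENE2"; breakpoints are "contig:position:strand".

All parsers convert the 5' breakpoint to the 0-based coordinate of the last
retained base and the 3' breakpoint to the 0-based coordinate of the first
retained base.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ConfigError, InputFormatError
from .reference_io import TranscriptModel

logger = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

IN_FRAME = "in_frame"
OUT_OF_FRAME = "out_of_frame"
UNKNOWN = "unknown"

DIALECTS = ("dialect_A", "dialect_F", "dialect_S")

#: caller vocabulary -> normalized frame label; stop-codon flavored labels
#: imply a disrupted frame and map to out_of_frame.
_FRAME_VOCAB = {
    "in-frame": IN_FRAME,
    "in_frame": IN_FRAME,
    "inframe": IN_FRAME,
    "out-of-frame": OUT_OF_FRAME,
    "out_of_frame": OUT_OF_FRAME,
    "frameshift": OUT_OF_FRAME,
    "stop-codon": OUT_OF_FRAME,
    "stop_codon": OUT_OF_FRAME,
    "premature_stop_codon": OUT_OF_FRAME,
}


def normalize_frame_label(raw: Optional[str]) -> str:
    if raw is None:
        return UNKNOWN
    return _FRAME_VOCAB.get(str(raw).strip().lower(), UNKNOWN)


@dataclass(frozen=True)
class Breakpoint:
    contig: str
    position: int  # 0-based; last retained base (5') / first retained base (3')
    gene_name: str
    strand: str  # transcribed orientation of the retained fragment
    retained_side: str
    transcript_id: Optional[str] = None
    exon_rank: Optional[int] = None

    def __post_init__(self):
        if self.retained_side not in (FIVE_PRIME, THREE_PRIME):
            raise InputFormatError(
                f"invalid retained_side {self.retained_side!r}"
            )
        if self.strand not in "+-":
            raise InputFormatError(f"invalid strand {self.strand!r}")
        if self.position < 0:
            raise InputFormatError(f"negative position {self.position}")


@dataclass(frozen=True)
class FusionCall:
    five_prime: Breakpoint
    three_prime: Breakpoint
    caller_name: str
    split_reads: int = 0
    spanning_pairs: int = 0
    caller_frame_prediction: str = UNKNOWN
    caller_frame_raw: Optional[str] = None

    def __post_init__(self):
        if self.five_prime.retained_side != FIVE_PRIME:
            raise InputFormatError("five_prime breakpoint has wrong retained_side")
        if self.three_prime.retained_side != THREE_PRIME:
            raise InputFormatError("three_prime breakpoint has wrong retained_side")
        if self.split_reads < 0 or self.spanning_pairs < 0:
            raise InputFormatError("evidence counts must be >= 0")

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.five_prime.gene_name, self.three_prime.gene_name)


@dataclass
class HarmonizedFusion:
    """Calls for one ordered gene pair merged across callers."""

    gene_pair: tuple[str, str]
    calls: tuple[FusionCall, ...]
    in_strand: Optional[bool] = None

    @property
    def concordance_count(self) -> int:
        return len({c.caller_name for c in self.calls})

    @property
    def fusion_id(self) -> str:
        return f"{self.gene_pair[0]}::{self.gene_pair[1]}"

    @property
    def representative(self) -> FusionCall:
        """Deterministic representative: lexicographically first caller."""
        return min(self.calls, key=lambda c: (c.caller_name, c.five_prime.position))

    @property
    def five_prime(self) -> Breakpoint:
        bp = self.representative.five_prime
        # prefer a call that carries exon/transcript annotation
        for call in sorted(self.calls, key=lambda c: c.caller_name):
            if call.five_prime.exon_rank is not None or call.five_prime.transcript_id:
                return call.five_prime
        return bp

    @property
    def three_prime(self) -> Breakpoint:
        for call in sorted(self.calls, key=lambda c: c.caller_name):
            if (
                call.three_prime.exon_rank is not None
                or call.three_prime.transcript_id
            ):
                return call.three_prime
        return self.representative.three_prime

    @property
    def split_reads(self) -> int:
        return max(c.split_reads for c in self.calls)

    @property
    def spanning_pairs(self) -> int:
        return max(c.spanning_pairs for c in self.calls)

    @property
    def caller_frame_predictions(self) -> dict[str, str]:
        return {c.caller_name: c.caller_frame_prediction for c in self.calls}

    def evidence_summary(self) -> str:
        parts = [
            f"{c.caller_name}:split={c.split_reads},span={c.spanning_pairs}"
            for c in sorted(self.calls, key=lambda c: c.caller_name)
        ]
        return ";".join(parts)


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

def _parse_locus(text: str, what: str) -> tuple[str, int, Optional[str]]:
    """Parse "contig:pos" or "contig:pos:strand" (1-based) -> 0-based."""
    parts = str(text).split(":")
    if len(parts) not in (2, 3):
        raise InputFormatError(f"cannot parse {what} locus {text!r}")
    contig, pos = parts[0], parts[1]
    try:
        position = int(pos) - 1
    except ValueError as exc:
        raise InputFormatError(f"non-numeric position in {what} {text!r}") from exc
    strand = parts[2] if len(parts) == 3 else None
    if strand is not None and strand not in "+-":
        raise InputFormatError(f"invalid strand in {what} {text!r}")
    return contig, position, strand


def _int_or_zero(value, column: str) -> int:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        logger.warning("missing evidence field %s; defaulting to 0", column)
        return 0
    return int(value)


def _read_table(path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    except Exception as exc:
        raise InputFormatError(f"cannot parse fusion table {path}: {exc}") from exc
    table.columns = [c.lstrip("#") for c in table.columns]
    return table


def _rows_a(table: pd.DataFrame) -> Iterable[FusionCall]:
    for _, row in table.iterrows():
        contig1, pos1, _ = _parse_locus(row["breakpoint1"], "breakpoint1")
        contig2, pos2, _ = _parse_locus(row["breakpoint2"], "breakpoint2")
        strand1 = str(row["strand1(gene/fusion)"]).split("/")[-1]
        strand2 = str(row["strand2(gene/fusion)"]).split("/")[-1]
        split = _int_or_zero(row.get("split_reads1"), "split_reads1") + _int_or_zero(
            row.get("split_reads2"), "split_reads2"
        )
        raw_frame = row.get("reading_frame")
        yield FusionCall(
            five_prime=Breakpoint(
                contig=contig1,
                position=pos1,
                gene_name=str(row["gene1"]),
                strand=strand1,
                retained_side=FIVE_PRIME,
                transcript_id=row.get("transcript_id1") or None,
            ),
            three_prime=Breakpoint(
                contig=contig2,
                position=pos2,
                gene_name=str(row["gene2"]),
                strand=strand2,
                retained_side=THREE_PRIME,
                transcript_id=row.get("transcript_id2") or None,
            ),
            caller_name="dialect_A",
            split_reads=split,
            spanning_pairs=_int_or_zero(row.get("discordant_mates"), "discordant_mates"),
            caller_frame_prediction=normalize_frame_label(raw_frame),
            caller_frame_raw=None if raw_frame is None else str(raw_frame),
        )


def _exon_rank_from_id(exon_id) -> Optional[int]:
    """FusionCatcher-style exon ids end in the exon number (e.g. GENE:exon18)."""
    if exon_id is None or (isinstance(exon_id, float) and pd.isna(exon_id)):
        return None
    text = str(exon_id)
    digits = ""
    for ch in reversed(text):
        if ch.isdigit():
            digits = ch + digits
        else:
            break
    return int(digits) if digits else None


def _rows_f(table: pd.DataFrame) -> Iterable[FusionCall]:
    g1 = "Gene_1_symbol(5end_fusion_partner)"
    g2 = "Gene_2_symbol(3end_fusion_partner)"
    p1 = "Fusion_point_for_gene_1(5end_fusion_partner)"
    p2 = "Fusion_point_for_gene_2(3end_fusion_partner)"
    for _, row in table.iterrows():
        contig1, pos1, strand1 = _parse_locus(row[p1], "fusion point 1")
        contig2, pos2, strand2 = _parse_locus(row[p2], "fusion point 2")
        if strand1 is None or strand2 is None:
            raise InputFormatError("dialect_F fusion points must carry a strand")
        raw_frame = row.get("Predicted_effect")
        yield FusionCall(
            five_prime=Breakpoint(
                contig=contig1,
                position=pos1,
                gene_name=str(row[g1]),
                strand=strand1,
                retained_side=FIVE_PRIME,
                exon_rank=_exon_rank_from_id(
                    row.get("Exon_1_id(5end_fusion_partner)")
                ),
            ),
            three_prime=Breakpoint(
                contig=contig2,
                position=pos2,
                gene_name=str(row[g2]),
                strand=strand2,
                retained_side=THREE_PRIME,
                exon_rank=_exon_rank_from_id(
                    row.get("Exon_2_id(3end_fusion_partner)")
                ),
            ),
            caller_name="dialect_F",
            split_reads=_int_or_zero(
                row.get("Spanning_unique_reads"), "Spanning_unique_reads"
            ),
            spanning_pairs=_int_or_zero(row.get("Spanning_pairs"), "Spanning_pairs"),
            caller_frame_prediction=normalize_frame_label(raw_frame),
            caller_frame_raw=None if raw_frame is None else str(raw_frame),
        )


def _rows_s(table: pd.DataFrame) -> Iterable[FusionCall]:
    for _, row in table.iterrows():
        name = str(row["FusionName"])
        if "--" not in name:
            raise InputFormatError(f"cannot parse FusionName {name!r}")
        gene1, gene2 = name.split("--", 1)
        contig1, pos1, strand1 = _parse_locus(row["LeftBreakpoint"], "LeftBreakpoint")
        contig2, pos2, strand2 = _parse_locus(row["RightBreakpoint"], "RightBreakpoint")
        if strand1 is None or strand2 is None:
            raise InputFormatError("dialect_S breakpoints must carry a strand")
        yield FusionCall(
            five_prime=Breakpoint(
                contig=contig1,
                position=pos1,
                gene_name=gene1,
                strand=strand1,
                retained_side=FIVE_PRIME,
            ),
            three_prime=Breakpoint(
                contig=contig2,
                position=pos2,
                gene_name=gene2,
                strand=strand2,
                retained_side=THREE_PRIME,
            ),
            caller_name="dialect_S",
            split_reads=_int_or_zero(row.get("JunctionReadCount"), "JunctionReadCount"),
            spanning_pairs=_int_or_zero(
                row.get("SpanningFragCount"), "SpanningFragCount"
            ),
            caller_frame_prediction=UNKNOWN,
        )


_PARSERS = {"dialect_A": _rows_a, "dialect_F": _rows_f, "dialect_S": _rows_s}


def read_fusion_calls(path: str | os.PathLike, dialect: str) -> list[FusionCall]:
    """Parse a caller table into normalized :class:`FusionCall` records.

    Rows whose coordinates cannot be parsed are rejected with a logged
    message; an empty table (header only) yields an empty list.
    """
    if dialect not in _PARSERS:
        raise ConfigError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    table = _read_table(path)
    if table.empty:
        return []
    calls = []
    rows = table.to_dict("records")
    for i, row in enumerate(rows):
        try:
            calls.extend(_PARSERS[dialect](pd.DataFrame([row])))
        except KeyError as exc:
            raise InputFormatError(
                f"{path}: missing column {exc} for {dialect}"
            ) from exc
        except InputFormatError as exc:
            logger.warning("%s row %d rejected: %s", path, i, exc)
    return calls


CALL_TSV_COLUMNS = (
    "gene_5p",
    "gene_3p",
    "contig_5p",
    "position_5p",
    "strand_5p",
    "contig_3p",
    "position_3p",
    "strand_3p",
    "caller",
    "split_reads",
    "spanning_pairs",
    "caller_frame",
)


def write_fusion_calls(calls: Sequence[FusionCall], path: str | os.PathLike) -> None:
    """Write normalized calls as TSV (positions 1-based in the file)."""
    rows = [
        {
            "gene_5p": c.five_prime.gene_name,
            "gene_3p": c.three_prime.gene_name,
            "contig_5p": c.five_prime.contig,
            "position_5p": c.five_prime.position + 1,
            "strand_5p": c.five_prime.strand,
            "contig_3p": c.three_prime.contig,
            "position_3p": c.three_prime.position + 1,
            "strand_3p": c.three_prime.strand,
            "caller": c.caller_name,
            "split_reads": c.split_reads,
            "spanning_pairs": c.spanning_pairs,
            "caller_frame": c.caller_frame_prediction,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def harmonize(calls: Sequence[FusionCall], window_nt: int = 10) -> list[HarmonizedFusion]:
    """Merge calls reporting the same ordered gene pair with both breakpoints
    within ``window_nt`` (single-linkage components, order independent)."""
    if window_nt < 0:
        raise ConfigError("window_nt must be >= 0")
    by_pair: dict[tuple[str, str], list[FusionCall]] = {}
    for call in calls:
        by_pair.setdefault(call.gene_pair, []).append(call)

    fusions = []
    for pair in sorted(by_pair):
        group = sorted(
            by_pair[pair],
            key=lambda c: (c.five_prime.position, c.three_prime.position, c.caller_name),
        )
        parent = list(range(len(group)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                if (
                    a.five_prime.contig == b.five_prime.contig
                    and a.three_prime.contig == b.three_prime.contig
                    and abs(a.five_prime.position - b.five_prime.position) <= window_nt
                    and abs(a.three_prime.position - b.three_prime.position)
                    <= window_nt
                ):
                    parent[find(i)] = find(j)
        clusters: dict[int, list[FusionCall]] = {}
        for i, call in enumerate(group):
            clusters.setdefault(find(i), []).append(call)
        for members in clusters.values():
            fusions.append(HarmonizedFusion(gene_pair=pair, calls=tuple(members)))
    fusions.sort(
        key=lambda f: (f.gene_pair, f.representative.five_prime.position)
    )
    return fusions


def check_in_strand(
    fusion: HarmonizedFusion | FusionCall,
    models: Sequence[TranscriptModel],
) -> Optional[bool]:
    """True iff both retained fragments are transcribed in the sense
    orientation of their annotated genes, so a single chimeric transcript can
    read through the junction.  Returns ``None`` (indeterminate) when a
    partner gene is absent from the annotation."""
    bp5 = fusion.five_prime
    bp3 = fusion.three_prime

    def annotated_strand(gene_name: str) -> Optional[str]:
        strands = {
            m.strand
            for m in models
            if m.gene_name.upper() == gene_name.upper() or m.gene_id == gene_name
        }
        if not strands:
            return None
        if len(strands) > 1:
            logger.warning("gene %s annotated on both strands", gene_name)
            return None
        return strands.pop()

    s5 = annotated_strand(bp5.gene_name)
    s3 = annotated_strand(bp3.gene_name)
    if s5 is None or s3 is None:
        return None
    return bp5.strand == s5 and bp3.strand == s3
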