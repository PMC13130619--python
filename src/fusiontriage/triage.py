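"""Five-criterion triage of harmonized fusions.

Criteria:

* C1 - the 3' partner is a druggable kinase gene,
* C2 - strand orientation is in-strand,
* C3 - the recomputed junction reading frame is out-of-frame,
* C4 - the kinase domain of the 3' partner is preserved,
* C5 - a 5'/3' expression imbalance is present in both partners.

C3 is decided by recomputation; caller frame labels are recorded so that
fusions the callers annotated out-of-frame but that recompute in-frame are
flagged as reclassified.  Indeterminate statuses propagate into a separate
``needs_input`` stratum instead of silently filtering a fusion.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import AnnotationError, CoordinateError, FusionTriageError
from .frame_rescue import (
    FrameVerdict,
    OrfPrediction,
    build_fusion_transcript,
    classify_frame,
    scan_downstream_starts,
)
from .fusion_calls import (
    FIVE_PRIME,
    IN_FRAME,
    OUT_OF_FRAME,
    THREE_PRIME,
    UNKNOWN,
    HarmonizedFusion,
    check_in_strand,
)
from .imbalance import ExonCountVector, FusionImbalanceResult, assess_fusion
from .reference_io import (
    DomainAnnotation,
    DruggableGeneList,
    GenomeSequence,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

PASS = "pass"
FAIL = "fail"
INDETERMINATE = "indeterminate"

CLASS_CANDIDATE = "candidate_functional_out_of_frame"
CLASS_IN_FRAME_IMBALANCED = "in_frame_imbalanced_candidate"
CLASS_FILTERED = "filtered"

CRITERION_NAMES = {
    "C1": "druggable kinase 3' partner",
    "C2": "in-strand orientation",
    "C3": "recomputed out-of-frame",
    "C4": "kinase domain preserved",
    "C5": "5'/3' expression imbalance",
}

#: editable default druggable-kinase list (users may supply their own)
DEFAULT_DRUGGABLE_KINASES = (
    "ALK",
    "RET",
    "ROS1",
    "NTRK1",
    "NTRK2",
    "NTRK3",
    "LTK",
    "EGFR",
    "BRAF",
    "RAF1",
    "MET",
    "ERBB2",
    "PDGFRA",
    "PDGFRB",
    "FGFR1",
    "FGFR2",
    "FGFR3",
    "KIT",
    "ABL1",
    "JAK2",
)


@dataclass
class TriageConfig:
    alpha: float = 0.05
    merge_window_nt: int = 10
    min_nonzero_exons: int = 2
    require_direction: bool = False
    partial_domain: bool = False
    breakpoint_opposite: bool = False
    max_starts: int = 10
    test_mode: str = "auto"
    alternative: str = "two_sided"


@dataclass(frozen=True)
class CriterionResult:
    criterion_id: str
    name: str
    status: str  # pass | fail | indeterminate
    evidence: str


@dataclass
class TriageVerdict:
    fusion_id: str
    criteria: dict[str, CriterionResult]
    recomputed_frame: str
    caller_frame: dict[str, str]
    reclassified: bool
    final_class: str
    needs_input: bool
    concordance_count: int
    rescue_predictions: list[OrfPrediction] = field(default_factory=list)
    frame_verdict: Optional[FrameVerdict] = None
    imbalance: Optional[FusionImbalanceResult] = None


def _criterion(cid: str, status: str, evidence: str) -> CriterionResult:
    logger.info("criterion %s (%s): %s -- %s", cid, CRITERION_NAMES[cid], status, evidence)
    return CriterionResult(
        criterion_id=cid, name=CRITERION_NAMES[cid], status=status, evidence=evidence
    )


def evaluate_criteria(
    fusion: HarmonizedFusion,
    models: Sequence[TranscriptModel],
    genome: GenomeSequence,
    domains: Sequence[DomainAnnotation],
    gene_list: DruggableGeneList,
    counts: Optional[dict[str, ExonCountVector]] = None,
    config: Optional[TriageConfig] = None,
) -> TriageVerdict:
    """Evaluate C1..C5 for one harmonized fusion.

    ``counts`` maps gene name to its :class:`ExonCountVector` (breakpoint
    fields may be unset; they are filled in from the fusion).  Unresolvable
    inputs yield indeterminate criterion statuses, never silent passes.
    """
    config = config or TriageConfig()
    gene5, gene3 = fusion.gene_pair
    criteria: dict[str, CriterionResult] = {}

    # C1 -- druggable kinase 3' partner
    in_list = gene3 in gene_list
    criteria["C1"] = _criterion(
        "C1",
        PASS if in_list else FAIL,
        f"3' partner {gene3} {'in' if in_list else 'not in'} druggable kinase list",
    )

    # C2 -- in-strand
    in_strand = check_in_strand(fusion, models)
    if in_strand is None:
        criteria["C2"] = _criterion(
            "C2", INDETERMINATE, "partner gene absent from annotation"
        )
    else:
        criteria["C2"] = _criterion(
            "C2",
            PASS if in_strand else FAIL,
            f"reported orientations {'are' if in_strand else 'are not'} compatible "
            "with a sense chimeric transcript",
        )

    # C3 / C4 -- frame recomputation and domain preservation
    recomputed = UNKNOWN
    verdict: Optional[FrameVerdict] = None
    predictions: list[OrfPrediction] = []
    ft = None
    try:
        ft = build_fusion_transcript(fusion, models, genome)
        verdict = classify_frame(ft)
        recomputed = verdict.status
        predictions = scan_downstream_starts(
            ft,
            domains,
            max_starts=config.max_starts,
            partial_domain=config.partial_domain,
        )
    except (AnnotationError, CoordinateError, FusionTriageError) as exc:
        logger.warning("frame recomputation failed for %s: %s", fusion.fusion_id, exc)
        criteria["C3"] = _criterion("C3", INDETERMINATE, f"recomputation failed: {exc}")
        criteria["C4"] = _criterion("C4", INDETERMINATE, f"recomputation failed: {exc}")

    if ft is not None:
        if recomputed == OUT_OF_FRAME:
            evidence = "recomputed out_of_frame"
            if verdict.stop_distance_codons is not None:
                evidence += (
                    f"; first stop {verdict.stop_distance_codons} codons past junction"
                )
            criteria["C3"] = _criterion("C3", PASS, evidence)
        elif recomputed == IN_FRAME:
            criteria["C3"] = _criterion("C3", FAIL, "recomputed in_frame")
        else:
            criteria["C3"] = _criterion(
                "C3", INDETERMINATE, "ATG1 not retained; frame indeterminate"
            )

        first_residue = ft.three_prime_protein_offset
        gene_domains = [
            d for d in domains if d.gene_name.upper() == gene3.upper()
        ]
        if not gene_domains:
            criteria["C4"] = _criterion(
                "C4", INDETERMINATE, f"no domain annotation for {gene3}"
            )
        elif first_residue is None:
            criteria["C4"] = _criterion(
                "C4", INDETERMINATE, "first retained residue undefined"
            )
        else:
            bound = "end_residue" if config.partial_domain else "start_residue"
            preserved = any(
                first_residue <= getattr(d, bound) for d in gene_domains
            )
            criteria["C4"] = _criterion(
                "C4",
                PASS if preserved else FAIL,
                f"first retained residue {first_residue} vs domain "
                + ", ".join(
                    f"{d.domain_name} {d.start_residue}-{d.end_residue}"
                    for d in gene_domains
                ),
            )

    # C5 -- expression imbalance
    imbalance_result: Optional[FusionImbalanceResult] = None
    vec5 = counts.get(gene5) if counts else None
    vec3 = counts.get(gene3) if counts else None
    if vec5 is None or vec3 is None:
        criteria["C5"] = _criterion(
            "C5", INDETERMINATE, "exon counts unavailable for one or both partners"
        )
    else:
        try:
            bp_rank5 = _breakpoint_exon_rank(fusion, models, FIVE_PRIME, ft)
            bp_rank3 = _breakpoint_exon_rank(fusion, models, THREE_PRIME, ft)
            vec5 = vec5.with_breakpoint(bp_rank5, FIVE_PRIME)
            vec3 = vec3.with_breakpoint(bp_rank3, THREE_PRIME)
            imbalance_result = assess_fusion(
                vec5,
                vec3,
                alpha=config.alpha,
                mode=config.test_mode,
                alternative=config.alternative,
                min_nonzero=config.min_nonzero_exons,
                require_direction=config.require_direction,
                breakpoint_opposite=config.breakpoint_opposite,
            )
        except (FusionTriageError, ValueError) as exc:
            criteria["C5"] = _criterion("C5", INDETERMINATE, f"imbalance failed: {exc}")
        else:
            if (
                imbalance_result.five_prime.indeterminate
                or imbalance_result.three_prime.indeterminate
            ):
                criteria["C5"] = _criterion(
                    "C5", INDETERMINATE, imbalance_result.reason or "indeterminate"
                )
            else:
                p5 = imbalance_result.five_prime.p_value
                p3 = imbalance_result.three_prime.p_value
                criteria["C5"] = _criterion(
                    "C5",
                    PASS if imbalance_result.overall_verdict else FAIL,
                    f"p_5p={p5:.4g}, p_3p={p3:.4g}, dual-gene rule "
                    f"{'met' if imbalance_result.overall_verdict else 'not met'}",
                )

    caller_frames = fusion.caller_frame_predictions
    reclassified = recomputed == IN_FRAME and any(
        lbl == OUT_OF_FRAME for lbl in caller_frames.values()
    )

    statuses = {cid: c.status for cid, c in criteria.items()}
    needs_input = any(s == INDETERMINATE for s in statuses.values())
    rescue_ok = any(
        p.frame_restoring and p.kinase_domain_covered and p.start_label != "ATG1"
        for p in predictions
    )
    if (
        all(s == PASS for s in statuses.values())
        and recomputed == OUT_OF_FRAME
        and rescue_ok
    ):
        final = CLASS_CANDIDATE
    elif (
        recomputed == IN_FRAME
        and statuses.get("C5") == PASS
        and statuses.get("C1") == PASS
        and statuses.get("C2") == PASS
        and statuses.get("C4") == PASS
    ):
        final = CLASS_IN_FRAME_IMBALANCED
    else:
        final = CLASS_FILTERED

    return TriageVerdict(
        fusion_id=fusion.fusion_id,
        criteria=criteria,
        recomputed_frame=recomputed,
        caller_frame=caller_frames,
        reclassified=reclassified,
        final_class=final,
        needs_input=needs_input,
        concordance_count=fusion.concordance_count,
        rescue_predictions=predictions,
        frame_verdict=verdict,
        imbalance=imbalance_result,
    )


def _breakpoint_exon_rank(
    fusion: HarmonizedFusion,
    models: Sequence[TranscriptModel],
    side: str,
    ft,
) -> int:
    """Exon rank containing the breakpoint on one side of the fusion."""
    bp = fusion.five_prime if side == FIVE_PRIME else fusion.three_prime
    if bp.exon_rank is not None:
        return bp.exon_rank
    if ft is not None:
        if side == FIVE_PRIME:
            return ft.five_model.exon_rank_at_offset(ft.cut5 - 1)
        return ft.three_exon_rank
    from .reference_io import select_transcript

    model = select_transcript(models, bp.gene_name, bp.transcript_id)
    return model.exon_rank_at_offset(model.genomic_to_transcript(bp.position))


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "fusion_id",
    "final_class",
    "needs_input",
    "reclassified",
    "recomputed_frame",
    "caller_frame",
    "concordance_count",
    "C1_status",
    "C2_status",
    "C3_status",
    "C4_status",
    "C5_status",
    "C1_evidence",
    "C2_evidence",
    "C3_evidence",
    "C4_evidence",
    "C5_evidence",
    "n_rescue_starts",
    "rescue_residues",
    "n_fusions_tested",
)


def _verdict_row(v: TriageVerdict, n_fusions: int) -> dict:
    rescue = [
        p.wildtype_start_residue
        for p in v.rescue_predictions
        if p.frame_restoring and p.start_label not in (None, "ATG1")
    ]
    row = {
        "fusion_id": v.fusion_id,
        "final_class": v.final_class,
        "needs_input": v.needs_input,
        "reclassified": v.reclassified,
        "recomputed_frame": v.recomputed_frame,
        "caller_frame": ";".join(
            f"{k}={val}" for k, val in sorted(v.caller_frame.items())
        ),
        "concordance_count": v.concordance_count,
        "n_rescue_starts": len(rescue),
        "rescue_residues": ",".join(str(r) for r in rescue),
        "n_fusions_tested": n_fusions,
    }
    for cid in ("C1", "C2", "C3", "C4", "C5"):
        crit = v.criteria.get(cid)
        row[f"{cid}_status"] = crit.status if crit else INDETERMINATE
        row[f"{cid}_evidence"] = crit.evidence if crit else "not evaluated"
    return row


def write_report(
    verdicts: Sequence[TriageVerdict], path: str | os.PathLike, format: str = "tsv"
) -> None:
    """Write one row/object per fusion; deterministic column and row order."""
    if format not in ("tsv", "json"):
        raise FusionTriageError(f"unknown report format {format!r}")
    ordered = sorted(verdicts, key=lambda v: v.fusion_id)
    if format == "tsv":
        rows = [_verdict_row(v, len(verdicts)) for v in ordered]
        pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    payload = []
    for v in ordered:
        payload.append(
            {
                "fusion_id": v.fusion_id,
                "final_class": v.final_class,
                "needs_input": v.needs_input,
                "reclassified": v.reclassified,
                "recomputed_frame": v.recomputed_frame,
                "caller_frame": dict(sorted(v.caller_frame.items())),
                "concordance_count": v.concordance_count,
                "criteria": {
                    cid: asdict(crit) for cid, crit in sorted(v.criteria.items())
                },
                "frame_verdict": asdict(v.frame_verdict) if v.frame_verdict else None,
                "rescue_predictions": [asdict(p) for p in v.rescue_predictions],
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report_json(path: str | os.PathLike) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)
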