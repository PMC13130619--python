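import dataclasses

import pytest
from Bio.Seq import Seq

from fusiontriage.errors import AnnotationError, CoordinateError
from fusiontriage import frame_rescue, synthetic
from fusiontriage.frame_rescue import (
    build_from_cdna,
    build_fusion_transcript,
    classify_frame,
    map_offset_to_residue,
    scan_downstream_starts,
    translate_prediction,
)
from fusiontriage.fusion_calls import (
    FIVE_PRIME,
    IN_FRAME,
    OUT_OF_FRAME,
    THREE_PRIME,
    Breakpoint,
    FusionCall,
    HarmonizedFusion,
    harmonize,
)
from fusiontriage.reference_io import GenomeSequence, spliced_sequence

from conftest import make_model

# Hand-built toy: two single-exon plus-strand genes.
#   gene5 transcript: AA ATG GGG CCC AAA TAA TT   (CDS [2, 17))
#   gene3 transcript: GG ATG GAT GCT AAG TGT TAA CC  (CDS [2, 20))
SEQ5 = "AAATGGGGCCCAAATAATT"
SEQ3 = "GGATGGATGCTAAGTGTTAACC"


@pytest.fixture
def toy():
    genome = GenomeSequence({"c5": SEQ5, "c3": SEQ3})
    model5 = make_model(
        gene="FIV", transcript="FIV.t1", contig="c5", exons=((0, len(SEQ5)),), cds=(2, 17)
    )
    model3 = make_model(
        gene="THR", transcript="THR.t1", contig="c3", exons=((0, len(SEQ3)),), cds=(2, 20)
    )
    return genome, [model5, model3]


def toy_fusion(pos5, pos3):
    return HarmonizedFusion(
        gene_pair=("FIV", "THR"),
        calls=(
            FusionCall(
                five_prime=Breakpoint(
                    contig="c5",
                    position=pos5,
                    gene_name="FIV",
                    strand="+",
                    retained_side=FIVE_PRIME,
                ),
                three_prime=Breakpoint(
                    contig="c3",
                    position=pos3,
                    gene_name="THR",
                    strand="+",
                    retained_side=THREE_PRIME,
                ),
                caller_name="dialect_A",
            ),
        ),
    )


class TestBuildFusionTranscript:
    def test_manual_concatenation(self, toy):
        genome, models = toy
        ft = build_fusion_transcript(toy_fusion(pos5=7, pos3=5), models, genome)
        assert ft.sequence == SEQ5[:8] + SEQ3[5:]
        assert ft.junction_offset == 8
        assert ft.cds_start_5p == 2

    def test_phase_zero_at_codon_boundary(self, toy):
        genome, models = toy
        ft = build_fusion_transcript(toy_fusion(7, 5), models, genome)
        assert ft.native_phase_3p == 0
        assert ft.three_prime_protein_offset == 2

    def test_breakpoint_one_nt_inside_codon(self, toy):
        genome, models = toy
        ft = build_fusion_transcript(toy_fusion(7, 6), models, genome)
        assert ft.native_phase_3p == 1
        # first fully retained codon is the following one
        assert ft.three_prime_protein_offset == 3

    def test_intronic_breakpoint_error(self, toy):
        genome, _ = toy
        two_exon = make_model(
            gene="FIV", transcript="FIV.t1", contig="c5", exons=((0, 6), (10, 18)),
            cds=(2, 12),
        )
        model3 = make_model(
            gene="THR", transcript="THR.t1", contig="c3", exons=((0, len(SEQ3)),),
            cds=(2, 20),
        )
        with pytest.raises(CoordinateError):
            build_fusion_transcript(toy_fusion(8, 5), [two_exon, model3], genome)

    def test_noncoding_three_prime_error(self, toy):
        genome, models = toy
        noncoding = dataclasses.replace(models[1], cds_start=None, cds_end=None)
        with pytest.raises(AnnotationError):
            build_fusion_transcript(toy_fusion(7, 5), [models[0], noncoding], genome)

    def test_coordinate_maps_are_strictly_increasing(self, toy):
        genome, models = toy
        ft = build_fusion_transcript(toy_fusion(7, 5), models, genome)
        fives = [ft.map_5p(o) for o in range(ft.junction_offset)]
        threes = [ft.map_3p(o) for o in range(ft.junction_offset, len(ft.sequence))]
        assert fives == sorted(set(fives))
        assert threes == sorted(set(threes))


class TestClassifyFrame:
    def test_phase_matched_in_frame(self, toy):
        genome, models = toy
        ft = build_fusion_transcript(toy_fusion(7, 5), models, genome)
        verdict = classify_frame(ft)
        assert verdict.status == IN_FRAME
        assert verdict.stop_distance_codons is None

    def test_phase_mismatch_out_of_frame(self, toy):
        genome, models = toy
        ft = build_fusion_transcript(toy_fusion(7, 6), models, genome)
        assert classify_frame(ft).status == OUT_OF_FRAME

    def test_atg1_lost_indeterminate(self, toy):
        genome, models = toy
        # retain only the first 2 bases of the 5' partner (upstream of ATG1)
        ft = build_fusion_transcript(toy_fusion(1, 5), models, genome)
        assert ft.cds_start_5p is None
        assert classify_frame(ft).status == "indeterminate"

    def test_engineered_stop_distance(self):
        for k in (1, 2, 5):
            cfg = synthetic.SimulationConfig(
                seed=11 + k,
                fusion=synthetic.FusionSpec(premature_stop_codons=k),
            )
            ef = synthetic.engineer_fusion(synthetic.make_toy_reference(cfg))
            ft = build_fusion_transcript(
                harmonize(ef.calls)[0], ef.reference.models, ef.reference.genome
            )
            assert classify_frame(ft).stop_distance_codons == k

    def test_oracle_agreement_over_randomized_fusions(self):
        """Brute-force oracle: translate from ATG1 and compare the peptide
        suffix with the wild-type 3' protein suffix."""
        n_checked = 0
        for seed in range(67):
            for shift in (0, 1, 2):
                cfg = synthetic.SimulationConfig(
                    seed=200 + seed,
                    fusion=synthetic.FusionSpec(
                        frame_shift=shift,
                        rescue_residues=() if shift == 0 else (250,),
                        premature_stop_codons=1 + seed % 6,
                        three_cut_phase=seed % 3,
                    ),
                )
                ref = synthetic.make_toy_reference(cfg)
                ef = synthetic.engineer_fusion(ref)
                ft = build_fusion_transcript(
                    harmonize(ef.calls)[0], ref.models, ref.genome
                )
                status = classify_frame(ft).status

                model3 = ref.model_of(cfg.three_gene.name)
                wt_cds = spliced_sequence(model3, ref.genome)[
                    model3.cds_start : model3.cds_end
                ]
                wt_protein = str(Seq(wt_cds).translate(to_stop=True))
                tail = ft.sequence[ft.cds_start_5p :]
                tail = tail[: len(tail) - len(tail) % 3]
                peptide = str(Seq(tail).translate(to_stop=True))
                suffix = wt_protein[ft.three_prime_protein_offset - 1 :]
                oracle_in_frame = len(suffix) > 0 and peptide.endswith(suffix)
                assert (status == IN_FRAME) == oracle_in_frame, (seed, shift)
                n_checked += 1
        assert n_checked == 201


class TestScanDownstreamStarts:
    @pytest.fixture
    def engineered(self):
        cfg = synthetic.SimulationConfig(seed=42)
        ref = synthetic.make_toy_reference(cfg)
        ef = synthetic.engineer_fusion(ref)
        ft = build_fusion_transcript(harmonize(ef.calls)[0], ref.models, ref.genome)
        return ref, ef, ft

    def test_planted_rescue_starts_recovered(self, engineered):
        ref, ef, ft = engineered
        preds = scan_downstream_starts(ft, ref.domains)
        restoring = [p for p in preds if p.frame_restoring and p.start_label != "ATG1"]
        assert [p.wildtype_start_residue for p in restoring] == [250, 274]
        assert [p.start_label for p in restoring] == ["ATG2", "ATG3"]
        assert all(p.kinase_domain_covered for p in restoring)

    def test_single_engineered_rescue(self):
        cfg = synthetic.SimulationConfig(
            seed=9, fusion=synthetic.FusionSpec(rescue_residues=(260,))
        )
        ref = synthetic.make_toy_reference(cfg)
        ef = synthetic.engineer_fusion(ref)
        ft = build_fusion_transcript(harmonize(ef.calls)[0], ref.models, ref.genome)
        restoring = [
            p
            for p in scan_downstream_starts(ft, ref.domains)
            if p.frame_restoring and p.start_label != "ATG1"
        ]
        (pred,) = restoring
        assert pred.wildtype_start_residue == 260

    def test_orf_ending_before_domain_not_covered(self, engineered):
        ref, ef, ft = engineered
        # brute-force translate all three frames of the fixture: non-restoring
        # ATGs terminate before the native stop and never cover the domain
        preds = scan_downstream_starts(ft, ref.domains)
        non_restoring = [p for p in preds if not p.frame_restoring]
        assert non_restoring, "fixture should contain non-restoring ATGs"
        for p in non_restoring:
            assert not p.kinase_domain_covered
            frame_seq = ft.sequence[p.start_offset :]
            pep = str(Seq(frame_seq[: len(frame_seq) - len(frame_seq) % 3]).translate())
            assert p.protein_length_aa == (
                pep.index("*") if "*" in pep else len(pep)
            )

    def test_rescue_after_domain_start_not_covered(self):
        cfg = synthetic.SimulationConfig(
            seed=13,
            fusion=synthetic.FusionSpec(rescue_residues=(300,)),
            domain_start_residue=290,
            domain_end_residue=345,
        )
        ref = synthetic.make_toy_reference(cfg)
        ef = synthetic.engineer_fusion(ref)
        ft = build_fusion_transcript(harmonize(ef.calls)[0], ref.models, ref.genome)
        (pred,) = [
            p
            for p in scan_downstream_starts(ft, ref.domains)
            if p.frame_restoring and p.start_label != "ATG1"
        ]
        assert pred.wildtype_start_residue == 300
        assert not pred.kinase_domain_covered

    def test_no_downstream_atg_yields_empty_tail(self):
        cfg = synthetic.SimulationConfig(
            seed=5,
            fusion=synthetic.FusionSpec(frame_shift=0, rescue_residues=()),
        )
        ref = synthetic.make_toy_reference(cfg)
        ef = synthetic.engineer_fusion(ref)
        ft = build_fusion_transcript(harmonize(ef.calls)[0], ref.models, ref.genome)
        preds = scan_downstream_starts(ft, ref.domains)
        restoring_downstream = [
            p for p in preds if p.frame_restoring and p.start_label != "ATG1"
        ]
        assert restoring_downstream == []

    def test_in_frame_atg1_runs_to_annotated_stop(self):
        cfg = synthetic.SimulationConfig(
            seed=6, fusion=synthetic.FusionSpec(frame_shift=0, rescue_residues=())
        )
        ref = synthetic.make_toy_reference(cfg)
        ef = synthetic.engineer_fusion(ref)
        ft = build_fusion_transcript(harmonize(ef.calls)[0], ref.models, ref.genome)
        atg1 = scan_downstream_starts(ft, ref.domains)[0]
        assert atg1.start_label == "ATG1"
        assert atg1.stop_offset is None  # runs to the annotated 3' stop

    def test_max_starts_truncation(self, engineered):
        ref, ef, ft = engineered
        preds = scan_downstream_starts(ft, ref.domains, max_starts=1)
        assert sum(p.frame_restoring and p.start_label != "ATG1" for p in preds) == 1

    def test_restoring_suffix_equals_wildtype_suffix(self, engineered):
        ref, ef, ft = engineered
        model3 = ref.model_of(ref.config.three_gene.name)
        wt_cds = spliced_sequence(model3, ref.genome)[model3.cds_start : model3.cds_end]
        wt_protein = str(Seq(wt_cds).translate(to_stop=True))
        for pred in scan_downstream_starts(ft, ref.domains):
            if not pred.frame_restoring or pred.start_label == "ATG1":
                continue
            pep = translate_prediction(ft, pred)
            assert pep == wt_protein[pred.wildtype_start_residue - 1 :]

    def test_mutating_first_rescue_atg_removes_only_that_prediction(self, engineered):
        ref, ef, ft = engineered
        preds = scan_downstream_starts(ft, ref.domains)
        restoring = [p for p in preds if p.frame_restoring and p.start_label != "ATG1"]
        first = restoring[0]
        mutated = (
            ft.sequence[: first.start_offset]
            + "CTC"
            + ft.sequence[first.start_offset + 3 :]
        )
        ft2 = dataclasses.replace(ft, sequence=mutated)
        restoring2 = [
            p
            for p in scan_downstream_starts(ft2, ref.domains)
            if p.frame_restoring and p.start_label != "ATG1"
        ]
        assert [p.wildtype_start_residue for p in restoring2] == [
            p.wildtype_start_residue for p in restoring[1:]
        ]


class TestMapOffsetToResidue:
    @pytest.fixture
    def ft(self):
        cfg = synthetic.SimulationConfig(seed=3)
        ref = synthetic.make_toy_reference(cfg)
        ef = synthetic.engineer_fusion(ref)
        return build_fusion_transcript(harmonize(ef.calls)[0], ref.models, ref.genome)

    def test_first_full_codon_identity(self, ft):
        phase = ft.native_phase_3p
        first_full = ft.junction_offset + ((3 - phase) % 3)
        assert map_offset_to_residue(ft, first_full) == ft.three_prime_protein_offset

    def test_unit_step(self, ft):
        phase = ft.native_phase_3p
        first_full = ft.junction_offset + ((3 - phase) % 3)
        assert (
            map_offset_to_residue(ft, first_full + 3)
            == map_offset_to_residue(ft, first_full) + 1
        )

    def test_72_nt_apart_is_24_residues(self, ft):
        phase = ft.native_phase_3p
        first_full = ft.junction_offset + ((3 - phase) % 3)
        assert (
            map_offset_to_residue(ft, first_full + 72)
            - map_offset_to_residue(ft, first_full)
            == 24
        )

    def test_off_grid_error(self, ft):
        phase = ft.native_phase_3p
        first_full = ft.junction_offset + ((3 - phase) % 3)
        with pytest.raises(CoordinateError):
            map_offset_to_residue(ft, first_full + 1)
        with pytest.raises(CoordinateError):
            map_offset_to_residue(ft, 0)


class TestBuildFromCdna:
    def test_junction_recovered_from_cdna(self):
        cfg = synthetic.SimulationConfig(seed=21)
        ref = synthetic.make_toy_reference(cfg)
        ef = synthetic.engineer_fusion(ref)
        model5 = ref.model_of(cfg.five_gene.name)
        model3 = ref.model_of(cfg.three_gene.name)
        ft = build_from_cdna(ef.cdna, model5, model3, ref.genome)
        assert ft.junction_offset == ef.truth.junction_offset
        assert ft.three_exon_rank == ef.truth.three_exon
        assert classify_frame(ft).status == ef.truth.frame_status

    @pytest.mark.parametrize("seed", [50, 51, 52, 53, 54, 55])
    def test_junction_microhomology_snaps_to_exon_boundary(self, seed):
        # when the last 5'-partner base equals the base preceding the 3' cut,
        # the suffix match overshoots the junction; the inferred 3' cut must
        # still land on the annotated exon boundary
        cfg = synthetic.SimulationConfig(seed=seed)
        ref = synthetic.make_toy_reference(cfg)
        ef = synthetic.engineer_fusion(ref)
        model5 = ref.model_of(cfg.five_gene.name)
        model3 = ref.model_of(cfg.three_gene.name)
        ft = build_from_cdna(ef.cdna, model5, model3, ref.genome)
        assert ft.three_exon_rank == ef.truth.three_exon
        assert ft.cut3 == ref.cut3

    def test_unrelated_cdna_rejected(self):
        cfg = synthetic.SimulationConfig(seed=22)
        ref = synthetic.make_toy_reference(cfg)
        model5 = ref.model_of(cfg.five_gene.name)
        model3 = ref.model_of(cfg.three_gene.name)
        with pytest.raises(AnnotationError):
            build_from_cdna("ACGT" * 30, model5, model3, ref.genome)
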