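import json

import numpy as np
import pytest

from matsplice.seqcore import SequenceRecord, translate_cds
from matsplice.splice import (
    GeneModelError,
    SpliceParams,
    UnrelatedTranscriptError,
    build_gene_model,
    classify_introns,
    classify_lesions,
    intron_phase,
    predict_protein_product,
    read_gene_model_gff3,
    read_gene_model_tsv,
    reference_protein,
    scan_intron_stops,
    write_gene_model_gff3,
    write_gene_model_tsv,
)
from matsplice.synthetic import (
    FixtureSpec,
    VariantPlan,
    make_gene_fixture,
    make_transcript_variant,
)


def toy_model(gene_seq="A" * 400, exons=((11, 100), (151, 250), (301, 390)),
              cds_start=11):
    gene = SequenceRecord(id="toy", residues=gene_seq)
    return build_gene_model(gene, exons, cds_start)


class TestGeneModel:
    def test_introns_derived_from_exon_gaps(self):
        model = toy_model()
        assert [(i.start, i.end) for i in model.introns] == [
            (101, 150), (251, 300)
        ]

    def test_single_exon_no_introns(self):
        model = toy_model(exons=((11, 100),))
        assert model.introns == ()

    def test_exon_intron_length_conservation(self, rng):
        for _ in range(30):
            fix = make_gene_fixture(FixtureSpec(seed=int(rng.integers(1e6))))
            model = fix.model
            span = model.exons[-1].end - model.exons[0].start + 1
            total = sum(len(e) for e in model.exons) + sum(
                len(i) for i in model.introns
            )
            assert total == span

    def test_overlapping_exons_rejected(self):
        with pytest.raises(GeneModelError):
            toy_model(exons=((11, 100), (90, 200)))

    def test_cds_start_outside_exon1_rejected(self):
        with pytest.raises(GeneModelError):
            toy_model(cds_start=120)


class TestIntronPhase:
    @pytest.mark.parametrize("upstream,phase", [(300, 0), (301, 1), (302, 2)])
    def test_phase_from_upstream_coding_length(self, upstream, phase):
        exons = ((1, upstream), (upstream + 51, upstream + 150))
        model = toy_model(gene_seq="A" * 600, exons=exons, cds_start=1)
        assert intron_phase(model, 1) == phase

    def test_phase_recurrence_on_random_models(self, rng):
        """phase(i) = (phase(i-1) + coding length of exon i) mod 3."""
        for _ in range(50):
            fix = make_gene_fixture(FixtureSpec(
                seed=int(rng.integers(1e6)),
                n_exons=int(rng.integers(2, 6)),
            ))
            model = fix.model
            for i in range(2, len(model.introns) + 1):
                expected = (
                    intron_phase(model, i - 1) + len(model.exons[i - 1])
                ) % 3
                assert intron_phase(model, i) == expected


class TestStopScan:
    def test_intron_start_ordinals(self):
        seq = "A" * 10 + "ATGGCC" + "TAAGGGTGA" + "GCCTGA" + "A" * 10
        gene = SequenceRecord(id="g", residues=seq)
        model = build_gene_model(gene, ((11, 16), (26, 31)), cds_start=11)
        scan = scan_intron_stops(model, 1, "intron_start")
        assert scan.stop_triplets == (1, 3)
        assert scan.stop_codons == ("TAA", "TGA")

    def test_no_stops_empty_scan(self):
        seq = "A" * 10 + "ATGGCC" + "GGGCCCGGG" + "GCCTGA" + "A" * 10
        gene = SequenceRecord(id="g", residues=seq)
        model = build_gene_model(gene, ((11, 16), (26, 31)), cds_start=11)
        assert scan_intron_stops(model, 1).stop_triplets == ()

    def test_junction_codon_mode_uses_carry_in(self):
        # upstream coding 7 nt -> phase 1; junction codon = 1 exon nt + GT
        seq = "A" * 10 + "ATGGCCA" + "GTAAGGG" + "GCCCTGA" + "A" * 10
        gene = SequenceRecord(id="g", residues=seq)
        model = build_gene_model(gene, ((11, 17), (25, 31)), cds_start=11)
        assert intron_phase(model, 1) == 1
        scan = scan_intron_stops(model, 1, "junction_codon")
        # scanned frame: AGT AAG GG. -> no stop; intron_start frame: GTA AGG
        assert scan.stop_triplets == ()
        scan2 = scan_intron_stops(model, 1, "intron_start")
        assert scan2.stop_triplets == ()

    def test_generator_seeded_ordinals_recovered(self):
        spec = FixtureSpec(seed=5, intron_stop_ordinals=((2, 7), None))
        fix = make_gene_fixture(spec)
        scan = scan_intron_stops(fix.model, 1, "intron_start")
        assert scan.stop_triplets == (2, 7)


class TestClassifyIntrons:
    def test_exon_concatenation_all_spliced(self, small_fixture):
        fix = small_fixture
        report = classify_introns(fix.model, fix.reference_transcript)
        assert [s.status for s in report.intron_statuses] == [
            "spliced" for _ in fix.model.introns
        ]
        assert report.indels == []
        assert report.prediction.clazz == "full"

    def test_full_gene_transcript_all_retained(self, small_fixture):
        fix = small_fixture
        tr = SequenceRecord(id="genomic", residues=fix.gene.residues)
        report = classify_introns(fix.model, tr)
        assert [s.status for s in report.intron_statuses] == [
            "retained" for _ in fix.model.introns
        ]

    def test_antisense_transcript_detected(self, small_fixture):
        from matsplice.seqcore import reverse_complement

        fix = small_fixture
        tr = SequenceRecord(
            id="rc", residues=reverse_complement(
                fix.reference_transcript.residues
            )
        )
        report = classify_introns(fix.model, tr)
        assert report.orientation == "-"
        assert report.prediction.clazz == "full"

    def test_unrelated_transcript_rejected(self, small_fixture, rng):
        junk = "".join(rng.choice(list("ACGT"), 500))
        with pytest.raises(UnrelatedTranscriptError):
            classify_introns(
                small_fixture.model, SequenceRecord(id="junk", residues=junk)
            )

    def test_mixed_retention_with_in_frame_deletion(self, small_fixture):
        fix = small_fixture
        plan = VariantPlan(
            splice_states=("retained", "spliced"),
            indels=((3, 54, "deletion"),),
            seed=9,
        )
        variant = make_transcript_variant(fix, plan)
        report = classify_introns(fix.model, variant.record)
        assert [s.status for s in report.intron_statuses] == [
            "retained", "spliced"
        ]
        (event,) = report.indels
        assert (event.kind, event.length, event.frame_class,
                event.codons_affected) == ("deletion", 54, "in_frame", 18)

    def test_spliced_implies_transcript_shorter(self, small_fixture):
        fix = small_fixture
        report = classify_introns(fix.model, fix.reference_transcript)
        for status, intron in zip(report.intron_statuses, fix.model.introns):
            assert status.status == "spliced"
            missing = len(fix.gene.residues) - len(
                fix.reference_transcript.residues
            )
            assert missing >= 0.9 * len(intron)


class TestPrediction:
    def test_unmutated_product_equals_exon_translation(self, small_fixture):
        fix = small_fixture
        report = classify_introns(fix.model, fix.reference_transcript)
        cds = fix.reference_transcript.residues
        assert report.prediction.product == translate_cds(cds).protein
        assert report.prediction.product == reference_protein(
            fix.model
        ).protein

    def test_retained_intron_phase0_arrest_length(self):
        """A stop at the first triplet of a retained phase-0 intron yields a
        product of exactly the upstream codon count."""
        fix = make_gene_fixture(FixtureSpec(
            seed=21, exon_length_range=(150, 150),  # 150 % 3 == 0 -> phase 0
            intron_stop_ordinals=((1,), (1,)),
        ))
        assert intron_phase(fix.model, 1) == 0
        plan = VariantPlan(splice_states=("retained", "spliced"), seed=2)
        variant = make_transcript_variant(fix, plan)
        report = classify_introns(fix.model, variant.record)
        assert report.prediction.clazz == "arrested"
        assert len(report.prediction.product) == 150 // 3
        assert report.prediction.arrest_codon == 150 // 3 + 1

    def test_five_prime_truncation_class(self, small_fixture):
        fix = small_fixture
        plan = VariantPlan(
            splice_states=tuple("spliced" for _ in fix.model.introns),
            truncate_5prime=100, seed=3,
        )
        variant = make_transcript_variant(fix, plan)
        report = classify_introns(fix.model, variant.record)
        assert report.prediction.clazz == "n_truncated"
        assert report.prediction.missing_n_terminal > 0

    def test_lesion_taxonomy(self):
        assert classify_lesions(False, False, False, 0) == "full"
        assert classify_lesions(True, False, False, 0) == "n_truncated"
        assert classify_lesions(False, True, False, 0) == "arrested"
        assert classify_lesions(False, False, True, 0) == "frameshifted"
        assert classify_lesions(False, False, False, 2) == "middle_truncated"
        assert classify_lesions(True, True, False, 0) == "compound"


class TestModelIO:
    def test_tsv_round_trip(self, small_fixture, tmp_path):
        path = tmp_path / "model.tsv"
        write_gene_model_tsv(small_fixture.model, path)
        back = read_gene_model_tsv(path, small_fixture.gene)
        assert back == small_fixture.model

    def test_gff3_round_trip(self, small_fixture, tmp_path):
        path = tmp_path / "model.gff3"
        write_gene_model_gff3(small_fixture.model, path)
        back = read_gene_model_gff3(path, small_fixture.gene)
        assert back == small_fixture.model

    def test_report_serialisation(self, small_fixture, tmp_path):
        report = classify_introns(
            small_fixture.model, small_fixture.reference_transcript
        )
        jpath = tmp_path / "report.json"
        report.to_json(jpath)
        payload = json.loads(jpath.read_text())
        assert payload["gene_id"] == small_fixture.gene.id
        assert len(payload["intron_statuses"]) == len(
            small_fixture.model.introns
        )
        tpath = tmp_path / "report.tsv"
        report.to_tsv(tpath)
        assert "intron" in tpath.read_text()
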