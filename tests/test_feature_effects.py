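import pytest

from mutprof import feature_effects as fe
from mutprof import synthetic_data as sd
from mutprof.variant_io import ExclusionLog, Mutation

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMPLEMENT)[::-1]


@pytest.fixture
def toy_annotation():
    tx = fe.TranscriptModel(
        transcript_id="tx1",
        chrom="chr1",
        strand="+",
        exons=((101, 160), (201, 300)),
        cds=((121, 160), (201, 280)),
        utr5=((101, 120),),
        utr3=((281, 300),),
    )
    return fe.GenomeAnnotation({"chr1": 100_000}, [tx])


def mut(pos, ref="A", alt="G", mclass="SBS", indel_len=0, line="L1"):
    return Mutation(line, "chr1", pos, ref, alt, mclass, "hom", indel_len)


class TestTranscriptModel:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            fe.TranscriptModel("t", "chr1", "+", exons=((1, 10), (5, 20)), cds=())

    def test_cds_offset_plus(self, toy_annotation):
        t = toy_annotation.transcripts[0]
        assert t.cds_offset(121) == 0
        assert t.cds_offset(160) == 39
        assert t.cds_offset(201) == 40
        assert t.cds_length == 120

    def test_cds_offset_minus(self):
        t = fe.TranscriptModel("t", "chr1", "-", exons=((10, 21),), cds=((10, 21),))
        assert t.cds_offset(21) == 0
        assert t.cds_offset(10) == 11

    def test_cds_overlap_length(self, toy_annotation):
        t = toy_annotation.transcripts[0]
        assert t.cds_overlap_length(150, 210) == 11 + 10
        assert t.cds_overlap_length(161, 200) == 0


class TestLocate:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (130, "exonic"),
            (121, "exonic"),
            (110, "UTR5"),
            (290, "UTR3"),
            (170, "intron"),
            (50, "upstream"),  # 500 bp 5' of a + strand transcript, window 1000
            (350, "downstream"),
            (5000, "intergenic"),
        ],
    )
    def test_categories(self, toy_annotation, pos, expected):
        assert fe.locate(mut(pos), toy_annotation) == expected

    def test_window_rule(self, toy_annotation):
        assert fe.locate(mut(100), toy_annotation, upstream_bp=1000) == "upstream"
        assert fe.locate(mut(100), toy_annotation, upstream_bp=0) == "intergenic"

    def test_minus_strand_upstream(self):
        t = fe.TranscriptModel("t", "chr1", "-", exons=((1000, 2000),), cds=((1000, 2000),))
        ann = fe.GenomeAnnotation({"chr1": 100_000}, [t])
        assert fe.locate(mut(2500), ann) == "upstream"
        assert fe.locate(mut(500), ann) == "downstream"

    def test_unknown_chromosome(self, toy_annotation):
        m = Mutation("L1", "chrX", 10, "A", "G", "SBS")
        with pytest.raises(KeyError):
            fe.locate(m, toy_annotation)

    def test_partition(self, small_fixture):
        muts = [
            Mutation(t.line_id, t.chrom, t.pos, t.ref, t.alt, t.mclass, "hom", t.indel_len)
            for t in small_fixture.truth
        ]
        table = fe.location_table(muts, small_fixture.annotation)
        total = sum(sum(row.values()) for row in table.values())
        assert total == len(muts)


class TestCodingEffectSbs:
    @pytest.fixture
    def plus_gene(self):
        # chr1: 5 bp pad + ATG AAA TAA + 5 bp pad
        genome = {"chr1": "GGGGG" + "ATGAAATAA" + "GGGGG"}
        t = fe.TranscriptModel("t", "chr1", "+", exons=((6, 14),), cds=((6, 14),))
        return genome, t

    def test_nonsense(self, plus_gene):
        genome, t = plus_gene
        call = fe.coding_effect_sbs(mut(9, "A", "T"), t, genome)  # AAA -> TAA
        assert call.category == "nonsense"
        assert call.codon_change == "AAA>TAA"
        assert call.aa_change == "K>*"

    def test_synonymous(self, plus_gene):
        genome, t = plus_gene
        call = fe.coding_effect_sbs(mut(11, "A", "G"), t, genome)  # AAA -> AAG (Lys)
        assert call.category == "synonymous"

    def test_nonsynonymous(self, plus_gene):
        genome, t = plus_gene
        call = fe.coding_effect_sbs(mut(9, "A", "C"), t, genome)  # AAA -> CAA (Gln)
        assert call.category == "nonsynonymous"

    def test_stop_loss_maps_to_nonsynonymous(self, plus_gene):
        genome, t = plus_gene
        log = ExclusionLog()
        call = fe.coding_effect_sbs(mut(13, "A", "C"), t, genome, log=log)  # TAA -> TCA
        assert call.category == "nonsynonymous"
        assert log.stop_loss_as_nonsyn == 1

    def test_minus_strand_matches_plus_oracle(self, plus_gene):
        genome_p, _ = plus_gene
        genome_m = {"chr1": revcomp(genome_p["chr1"])}
        t = fe.TranscriptModel("t", "chr1", "-", exons=((6, 14),), cds=((6, 14),))
        # coding A at CDS offset 3 (first base of codon 2) is genomic position 11
        pos = 14 - 3
        assert genome_m["chr1"][pos - 1] == "T"
        call = fe.coding_effect_sbs(mut(pos, "T", "A"), t, genome_m)  # coding A>T
        assert call.category == "nonsense"
        assert call.codon_change == "AAA>TAA"

    def test_ref_mismatch_errors(self, plus_gene):
        genome, t = plus_gene
        with pytest.raises(ValueError, match="mismatch"):
            fe.coding_effect_sbs(mut(9, "C", "T"), t, genome)

    def test_not_in_cds_errors(self, plus_gene):
        genome, t = plus_gene
        with pytest.raises(ValueError):
            fe.coding_effect_sbs(mut(2, "G", "A"), t, genome)


class TestCodingEffectIndel:
    def test_two_bp_deletion_frameshift(self, toy_annotation):
        t = toy_annotation.transcripts[0]
        m = mut(125, "ACG", "A", "DEL", 2)
        assert fe.coding_effect_indel(m, t).category == "frameshift"

    def test_three_bp_deletion_inframe(self, toy_annotation):
        t = toy_annotation.transcripts[0]
        m = mut(125, "ACGT", "A", "DEL", 3)
        assert fe.coding_effect_indel(m, t).category == "inframe_indel"

    def test_seven_bp_insertion_frameshift(self, toy_annotation):
        t = toy_annotation.transcripts[0]
        m = mut(125, "A", "ACGTACGT", "INS", 7)
        assert fe.coding_effect_indel(m, t).category == "frameshift"

    def test_boundary_deletion_counts_coding_overlap(self, toy_annotation):
        t = toy_annotation.transcripts[0]
        # deletes 160 (coding) plus 161-162 (intron): 1 coding base -> frameshift
        m = mut(159, "ACGT", "A", "DEL", 3)
        assert fe.coding_effect_indel(m, t).category == "frameshift"
        # deletes 158-160 (coding) plus 161-163 (intron): 3 coding bases -> inframe
        m = mut(157, "ACGTACG", "A", "DEL", 6)
        assert fe.coding_effect_indel(m, t).category == "inframe_indel"

    def test_no_cds_overlap_errors(self, toy_annotation):
        t = toy_annotation.transcripts[0]
        with pytest.raises(ValueError):
            fe.coding_effect_indel(mut(170, "AC", "A", "DEL", 1), t)


class TestClassifyAndTable:
    def test_intergenic_only_all_zero(self, toy_annotation):
        genome = {"chr1": "A" * 100_000}
        muts = [mut(50_000 + i, "A", "G", line="L1") for i in range(5)]
        table, calls = fe.effect_table(muts, toy_annotation, genome)
        assert calls == []
        assert all(v == 0 for v in table["L1"].values())

    def test_fixture_matches_truth_oracle(self, small_fixture):
        fx = small_fixture
        muts = [
            Mutation(t.line_id, t.chrom, t.pos, t.ref, t.alt, t.mclass, "hom", t.indel_len)
            for t in fx.truth
        ]
        oracle = {(t.line_id, t.chrom, t.pos, t.alt): t.oracle_effect for t in fx.truth}
        _, calls = fe.effect_table(muts, fx.annotation, fx.genome)
        got = {(c.line_id, c.chrom, c.pos, c.alt): c.category for c in calls}
        expected = {k: v for k, v in oracle.items() if v}
        assert got == expected

    def test_tie_break_deterministic(self):
        genome = {"chr1": "GG" + "ATGAAATAA" + "G" * 20}
        t1 = fe.TranscriptModel("tx_b", "chr1", "+", exons=((3, 11),), cds=((3, 11),))
        t2 = fe.TranscriptModel("tx_a", "chr1", "+", exons=((3, 11),), cds=((3, 11),))
        ann = fe.GenomeAnnotation({"chr1": len(genome["chr1"])}, [t1, t2])
        call = fe.classify_effect(mut(8, "A", "G"), ann, genome)  # synonymous in both
        assert call.transcript_id == "tx_a"

    def test_aggregate_effect_counts(self):
        per_line = {
            "a": {"synonymous": 2, "nonsynonymous": 1, "nonsense": 1, "frameshift": 0},
            "b": {"synonymous": 0, "nonsynonymous": 3, "nonsense": 1, "frameshift": 2},
        }
        totals, average, hi_total, hi_avg = fe.aggregate_effect_counts(per_line)
        assert totals == {"synonymous": 2, "nonsynonymous": 4, "nonsense": 2, "frameshift": 2}
        assert average["nonsynonymous"] == 2.0
        assert hi_total == 4 and hi_avg == 2.0


class TestStrandSymmetry:
    def test_effects_unchanged_under_reverse_complement(self, small_fixture):
        fx = small_fixture
        lengths = fx.annotation.contig_lengths

        def mirror_interval(chrom, s, e):
            L = lengths[chrom]
            return (L - e + 1, L - s + 1)

        genome_m = {c: revcomp(s) for c, s in fx.genome.items()}
        transcripts_m = [
            fe.TranscriptModel(
                transcript_id=t.transcript_id,
                chrom=t.chrom,
                strand="-" if t.strand == "+" else "+",
                exons=tuple(mirror_interval(t.chrom, s, e) for s, e in t.exons),
                cds=tuple(mirror_interval(t.chrom, s, e) for s, e in t.cds),
                utr5=tuple(mirror_interval(t.chrom, s, e) for s, e in t.utr5),
                utr3=tuple(mirror_interval(t.chrom, s, e) for s, e in t.utr3),
            )
            for t in fx.annotation.transcripts
        ]
        ann_m = fe.GenomeAnnotation(lengths, transcripts_m)
        coding_sbs = [t for t in fx.truth if t.mclass == "SBS" and t.oracle_effect]
        assert coding_sbs
        for t in coding_sbs:
            m = Mutation(t.line_id, t.chrom, t.pos, t.ref, t.alt, "SBS")
            fwd = fe.classify_effect(m, fx.annotation, fx.genome)
            pos_m = lengths[t.chrom] - t.pos + 1
            m2 = Mutation(
                t.line_id, t.chrom, pos_m,
                t.ref.translate(COMPLEMENT), t.alt.translate(COMPLEMENT), "SBS",
            )
            rev = fe.classify_effect(m2, ann_m, genome_m)
            assert rev is not None
            assert rev.category == fwd.category


class TestGff3Reader:
    def test_missing_contig_lengths_errors(self, tmp_path):
        p = tmp_path / "x.gff3"
        p.write_text("##gff-version 3\nchr1\tsrc\tgene\t1\t10\t.\t+\t.\tID=g1\n")
        with pytest.raises(ValueError, match="sequence-region"):
            fe.read_gff3(p)

    def test_round_trip_preserves_models(self, tmp_path):
        _, ann = sd.generate_genome(1, 30_000, 4, seed=13)
        path = tmp_path / "a.gff3"
        fe.write_gff3(path, ann)
        back = fe.read_gff3(path)
        assert back.contig_lengths == ann.contig_lengths
        assert sorted(back.transcripts, key=lambda t: t.transcript_id) == sorted(
            ann.transcripts, key=lambda t: t.transcript_id
        )
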