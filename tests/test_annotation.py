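import pytest

from _oracles import feature_of_center
from tscreg.annotation import (
    GeneAnnotation,
    GeneModel,
    RefFlatParseError,
    assign_targets,
    classify_feature,
    read_refflat,
    write_refflat,
)
from tscreg.intervals import Peak


def _row(
    name="G1",
    tx="tx1",
    chrom="chr1",
    strand="+",
    start=5000,
    end=9000,
    exons=((5000, 6000), (8000, 9000)),
):
    starts = ",".join(str(s) for s, _ in exons) + ","
    ends = ",".join(str(e) for _, e in exons) + ","
    return (
        f"{name}\t{tx}\t{chrom}\t{strand}\t{start}\t{end}\t{start}\t{end}\t"
        f"{len(exons)}\t{starts}\t{ends}\n"
    )


class TestReadRefflat:
    def test_plus_strand_tss_is_tx_start(self, tmp_path):
        path = tmp_path / "rf.txt"
        path.write_text(_row(strand="+", start=5000))
        ann = read_refflat(path)
        assert ann.genes[0].tss == 5000

    def test_minus_strand_tss_is_tx_end_minus_one(self, tmp_path):
        path = tmp_path / "rf.txt"
        path.write_text(_row(strand="-", start=5000, end=9000))
        ann = read_refflat(path)
        assert ann.genes[0].tss == 8999

    def test_exon_count_mismatch_names_row(self, tmp_path):
        bad = _row().replace("\t2\t", "\t3\t")
        path = tmp_path / "rf.txt"
        path.write_text(bad)
        with pytest.raises(RefFlatParseError, match=":1:"):
            read_refflat(path)

    def test_roundtrip(self, tmp_path, small_annotation):
        path = tmp_path / "rf.txt"
        write_refflat(small_annotation.genes, path)
        back = read_refflat(path)
        assert [(g.name, g.tss, g.exons) for g in back.genes] == [
            (g.name, g.tss, g.exons) for g in small_annotation.genes
        ]

    def test_symbol_lookup_returns_all_transcripts(self, tmp_path):
        path = tmp_path / "rf.txt"
        path.write_text(_row(tx="tx1") + _row(tx="tx2", start=7000, end=9500, exons=((7000, 9500),)))
        ann = read_refflat(path)
        assert len(ann.transcripts_of("G1")) == 2


class TestClassifyFeature:
    def test_promoter_beats_intron(self):
        # ALPHA's TSS at 10,000; the point 9,500 also lies in an intron of
        # a second overlapping gene
        ann = GeneAnnotation(
            [
                GeneModel("ALPHA", "t1", "chr1", "+", 10_000, 30_000, ((10_000, 30_000),)),
                GeneModel("HOST", "t2", "chr1", "+", 1_000, 20_000, ((1_000, 2_000), (19_000, 20_000))),
            ]
        )
        peak = Peak("chr1", 9_400, 9_600)
        assert classify_feature(peak, ann) == "promoter"

    def test_exon_center(self, small_annotation):
        peak = Peak("chr1", 20_500, 21_500)  # center 21,000 in ALPHA exon 2
        assert classify_feature(peak, small_annotation) == "exon"

    def test_intron_center(self, small_annotation):
        peak = Peak("chr1", 14_000, 15_000)
        assert classify_feature(peak, small_annotation) == "intron"

    def test_intergenic(self, small_annotation):
        assert classify_feature(Peak("chr1", 60_000, 60_200), small_annotation) == "intergenic"

    def test_matches_point_oracle_on_random_peaks(self, rng, small_annotation):
        tx_by_chrom = {}
        for g in small_annotation.genes:
            tx_by_chrom.setdefault(g.chrom, []).append(
                (g.tss, g.tx_start, g.tx_end, list(g.exons))
            )
        for _ in range(200):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            c = int(rng.integers(0, 150_000))
            peak = Peak(chrom, c, c + 2)  # center == c
            expected = feature_of_center(c, tx_by_chrom.get(chrom, []))
            assert classify_feature(peak, small_annotation) == expected


class TestAssignTargets:
    def test_tss_flank_with_signed_upstream_distance(self, small_annotation):
        # center 1 is ~10 kb upstream of ALPHA(+) TSS: distance 1 - 10000
        out = assign_targets([Peak("chr1", 0, 2)], small_annotation)
        alpha = [a for a in out if a.gene == "ALPHA"]
        assert alpha and alpha[0].via == "tss_flank"
        assert alpha[0].distance_to_tss == -9999

    def test_minus_strand_upstream_is_negative(self, small_annotation):
        # BETA(-) TSS at 119,999; center 125,000 is upstream for '-' strand
        out = assign_targets([Peak("chr1", 124_999, 125_001)], small_annotation)
        beta = [a for a in out if a.gene == "BETA"][0]
        assert beta.distance_to_tss == -(125_000 - 119_999)

    def test_gene_body_assignment_outside_flank(self):
        ann = GeneAnnotation(
            [GeneModel("LONG", "t", "chr1", "+", 0, 100_000, ((0, 100_000),))]
        )
        out = assign_targets([Peak("chr1", 49_999, 50_001)], ann, flank=20_000)
        assert out[0].via == "gene_body"

    def test_nearest_fallback_tie_rule(self):
        ann = GeneAnnotation(
            [
                GeneModel("FAR1", "t1", "chr1", "+", 150_001, 151_001, ((150_001, 151_001),)),
                GeneModel("FAR2", "t2", "chr1", "+", 49_999, 50_999, ((49_999, 50_999),)),
            ]
        )
        out = assign_targets([Peak("chr1", 99_999, 100_001)], ann, flank=20_000)
        assert len(out) == 1
        assert out[0].gene == "FAR2"  # 50,001 bp beats 50,001... the closer TSS
        assert out[0].via == "nearest_fallback"

    def test_no_genes_on_chromosome_skipped(self, small_annotation, caplog):
        out = assign_targets([Peak("chrX", 10, 20)], small_annotation)
        assert out == []

    def test_every_peak_assigned_with_fallback(self, rng, small_annotation):
        peaks = [Peak("chr1", int(s), int(s) + 10) for s in rng.integers(0, 500_000, 50)]
        out = assign_targets(peaks, small_annotation)
        assert len({(a.peak.start, a.peak.end) for a in out}) == 50

    def test_strand_flip_moves_promoter(self):
        plus = GeneModel("G", "t", "chr1", "+", 10_000, 30_000, ((10_000, 30_000),))
        minus = GeneModel("G", "t", "chr1", "-", 10_000, 30_000, ((10_000, 30_000),))
        near_start = Peak("chr1", 9_000, 9_200)
        assert classify_feature(near_start, GeneAnnotation([plus])) == "promoter"
        assert classify_feature(near_start, GeneAnnotation([minus])) == "intergenic"
        near_end = Peak("chr1", 30_500, 30_700)
        assert classify_feature(near_end, GeneAnnotation([minus])) == "promoter"
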