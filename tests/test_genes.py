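"""Transcript feature derivation and the annotation filtering/merging rules."""

import pytest

from mencrna.genes import (
    GeneModel,
    Transcript,
    derive_features,
    filter_transcripts,
    merge_annotations,
)
from mencrna.intervals import CaptureUniverse, GenomicInterval, merge_intervals


def iv(s, e, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, s, e, strand)


def gene(gid, exons, biotype="mencRNA", strand="+", chrom="chr1"):
    t = Transcript(f"{gid}.1", gid, tuple(iv(s, e, strand, chrom) for s, e in exons))
    return GeneModel(gid, [t], biotype)


class TestDeriveFeatures:
    def test_plus_strand_introns_and_upstream_promoter(self, two_exon_gene):
        fs = derive_features([two_exon_gene], promoter_mode="upstream500")
        assert [f.interval for f in fs.introns] == [iv(1100, 1200)]
        assert [f.interval for f in fs.promoters] == [iv(500, 1000)]

    def test_flank_promoter_is_tss_plus_minus_500(self, two_exon_gene):
        fs = derive_features([two_exon_gene], promoter_mode="flank500")
        (p,) = [f.interval for f in fs.promoters]
        assert (p.start, p.end) == (500, 1501)
        assert p.length == 1001

    def test_minus_strand_promoter_mirrors(self, minus_gene):
        fs = derive_features([minus_gene], promoter_mode="upstream500")
        (p,) = [f.interval for f in fs.promoters]
        assert (p.start, p.end) == (1300, 1800)

    def test_unstranded_upstream_promoter_errors_naming_transcript(self):
        g = gene("gu", [(100, 200), (300, 400)], strand=".")
        with pytest.raises(ValueError, match="gu.1"):
            derive_features([g], promoter_mode="upstream500")

    def test_promoter_truncated_at_chromosome_start(self):
        g = gene("g0", [(100, 200), (300, 400)])
        fs = derive_features([g], promoter_mode="flank500")
        (p,) = [f.interval for f in fs.promoters]
        assert p.start == 0 and p.end == 601

    def test_exon_intron_union_reconstructs_span(self, default_genome):
        _, genome = default_genome
        fs = derive_features(genome.genes, kinds=("exon", "intron"))
        by_t = {}
        for f in fs.exons + fs.introns:
            by_t.setdefault(f.transcript_id, []).append(f.interval)
        spans = {
            t.transcript_id: (t.start, t.end)
            for g in genome.genes
            for t in g.transcripts
        }
        for tid, ivs in by_t.items():
            merged = merge_intervals(ivs)
            assert len(merged) == 1
            assert (merged[0].start, merged[0].end) == spans[tid]

    def test_features_carry_gene_and_transcript_tags(self, two_exon_gene):
        fs = derive_features([two_exon_gene])
        assert all(f.gene_id == "g1" and f.transcript_id == "t1" for f in fs.exons)


class TestFilterTranscripts:
    universe = CaptureUniverse([GenomicInterval("chr1", 0, 10_000)])

    def test_single_exon_removed_despite_high_expression(self):
        g = gene("s1", [(100, 200)])
        kept, log = filter_transcripts([g], {"s1": 10.0}, {}, self.universe)
        assert kept == [] and ("s1", "single_exon") in log

    def test_low_expression_removed_at_half_fpkm(self):
        g = gene("lo", [(100, 200), (300, 400)])
        kept, log = filter_transcripts([g], {"lo": 0.4}, {}, self.universe)
        assert kept == [] and ("lo", "low_expression") in log

    def test_passing_gene_retained(self):
        g = gene("ok", [(100, 200), (300, 400)])
        kept, log = filter_transcripts([g], {"ok": 3.0}, {}, self.universe)
        assert [k.gene_id for k in kept] == ["ok"] and log == []

    def test_outside_capture_removed(self):
        g = gene("out", [(100, 200), (300, 400)], chrom="chr9")
        kept, log = filter_transcripts([g], {"out": 3.0}, {}, self.universe)
        assert kept == [] and ("out", "outside_capture") in log

    def test_same_strand_coding_overlap_removed(self):
        g = gene("cv", [(100, 200), (300, 400)])
        coding = [gene("pc", [(150, 160)], biotype="protein_coding")]
        kept, log = filter_transcripts([g], {"cv": 3.0}, {}, self.universe, coding)
        assert kept == [] and ("cv", "coding_overlap") in log

    def test_opposite_strand_coding_overlap_kept_here(self):
        g = gene("os", [(100, 200), (300, 400)], strand="+")
        coding = [gene("pc", [(150, 160)], biotype="protein_coding", strand="-")]
        kept, _ = filter_transcripts([g], {"os": 3.0}, {}, self.universe, coding)
        assert [k.gene_id for k in kept] == ["os"]

    def test_low_isoform_dropped_gene_survives(self):
        t_hi = Transcript("m.1", "m", (iv(100, 200), iv(300, 400)))
        t_lo = Transcript("m.2", "m", (iv(100, 200), iv(500, 600)))
        g = GeneModel("m", [t_hi, t_lo], "mencRNA")
        kept, log = filter_transcripts(
            [g], {"m": 3.0}, {"m.1": 3.0, "m.2": 0.005}, self.universe
        )
        assert [t.transcript_id for t in kept[0].transcripts] == ["m.1"]
        assert ("m.2", "low_isoform_expression") in log

    def test_missing_expression_is_input_error(self):
        g = gene("x", [(100, 200), (300, 400)])
        with pytest.raises(KeyError):
            filter_transcripts([g], {}, {}, self.universe)

    def test_idempotent(self, default_genome):
        _, genome = default_genome
        cands = [g for g in genome.genes if g.biotype == "mencRNA"]
        coding = [g for g in genome.genes if g.biotype == "protein_coding"]
        once, _ = filter_transcripts(
            cands, genome.gene_max_fpkm, genome.isoform_max_fpkm, genome.universe, coding
        )
        twice, log2 = filter_transcripts(
            once, genome.gene_max_fpkm, genome.isoform_max_fpkm, genome.universe, coding
        )
        assert [g.gene_id for g in once] == [g.gene_id for g in twice]
        assert log2 == []


class TestMergeAnnotations:
    def test_low_fpkm_captured_yields_to_reference(self):
        cap = gene("cap", [(100, 200), (300, 400)])
        ref = gene("ref", [(150, 250), (300, 350)], biotype="other")
        merged, log = merge_annotations([cap], {"cap": 0.3}, [ref])
        assert [g.gene_id for g in merged] == ["ref"]
        assert ("cap", "low_expression_vs_reference") in log

    def test_expressed_captured_supersedes_reference(self):
        cap = gene("cap", [(100, 200), (300, 400)])
        ref = gene("ref", [(150, 250), (300, 350)], biotype="other")
        merged, log = merge_annotations([cap], {"cap": 2.0}, [ref])
        assert [g.gene_id for g in merged] == ["cap"]
        assert ("ref", "superseded_by_captured") in log

    def test_one_bp_opposite_strand_coding_overlap_excludes_captured(self):
        cap = gene("cap", [(100, 200), (300, 400)], strand="+")
        # coding exon on - strand overlapping by exactly 1 bp
        ref = gene("pc", [(199, 300)], biotype="protein_coding", strand="-")
        merged, log = merge_annotations([cap], {"cap": 5.0}, [ref])
        assert all(g.gene_id != "cap" for g in merged)
        assert ("cap", "opposite_strand_coding_overlap") in log

    def test_non_overlapping_sets_concatenate(self):
        cap = gene("cap", [(100, 200), (300, 400)])
        ref = gene("ref", [(5000, 5100), (5200, 5300)], biotype="other")
        merged, log = merge_annotations([cap], {"cap": 2.0}, [ref])
        assert sorted(g.gene_id for g in merged) == ["cap", "ref"]
        assert log == []
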