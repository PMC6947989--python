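"""Fold enrichment, hypergeometric test, and the circular-permutation null."""

import itertools
import math

import numpy as np
import pytest

from mencrna.ccv import Variant, ccvs_in_feature
from mencrna.enrichment import (
    fold_enrichment,
    hypergeom_test,
    permutation_test,
    permute_annotation,
)
from mencrna.genes import GeneModel, Transcript, derive_features
from mencrna.intervals import CaptureUniverse, GenomicInterval, total_length


def iv(s, e, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, s, e, strand)


def var(pos, vid=None, chrom="chr1"):
    return Variant(vid or f"v{pos}", chrom, pos, 1e-8)


def single_transcript_gene(gid, exons, strand="+", chrom="chr1"):
    t = Transcript(
        f"{gid}.1", gid, tuple(iv(s, e, strand, chrom) for s, e in exons)
    )
    return GeneModel(gid, [t], "mencRNA")


class TestFoldEnrichment:
    universe = CaptureUniverse([iv(0, 1_000_000)])

    def test_null_expectation_is_one(self):
        # feature covers 10%, and exactly 10% of CCVs overlap it
        feature = [iv(0, 100_000)]
        ccvs = [var(50_000 + i) for i in range(10)] + [
            var(500_000 + i) for i in range(90)
        ]
        assert fold_enrichment(ccvs, feature, self.universe) == pytest.approx(1.0)

    def test_hand_arithmetic_fourfold(self):
        feature = [iv(0, 50_000)]
        ccvs = [var(i * 10) for i in range(20)] + [var(600_000 + i) for i in range(80)]
        assert fold_enrichment(ccvs, feature, self.universe) == pytest.approx(4.0)

    def test_empty_feature_gives_zero(self):
        assert fold_enrichment([var(10)], [], self.universe) == 0.0

    def test_out_of_universe_ccvs_dropped_with_warning(self):
        ccvs = [var(10), var(10, vid="far", chrom="chr9")]
        with pytest.warns(UserWarning, match="outside the capture universe"):
            fold = fold_enrichment(ccvs, [iv(0, 100)], self.universe)
        assert fold == pytest.approx(1.0 / (100 / 1_000_000))

    def test_all_ccvs_outside_universe_errors(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                fold_enrichment([var(5, chrom="chrX")], [iv(0, 100)], self.universe)


class TestHypergeomTest:
    def test_zero_successes_certain(self):
        assert hypergeom_test(0, 5, 100, 1000) == pytest.approx(1.0)

    def test_closed_form_small_case_and_enumeration(self):
        """20-bp universe, 10-bp feature, both of 2 CCVs inside: 45/190."""
        p = hypergeom_test(2, 2, 10, 20)
        assert p == pytest.approx(45 / 190, rel=1e-12)
        # independent oracle: enumerate all unordered position pairs
        inside = 0
        total = 0
        for a, b in itertools.combinations(range(20), 2):
            total += 1
            inside += a < 10 and b < 10
        assert p == pytest.approx(inside / total, rel=1e-12)

    def test_feature_equals_universe_certain(self):
        assert hypergeom_test(7, 7, 500, 500) == pytest.approx(1.0)

    def test_degenerate_totals_error(self):
        with pytest.raises(ValueError):
            hypergeom_test(0, 0, 10, 100)
        with pytest.raises(ValueError):
            hypergeom_test(3, 2, 10, 100)


class TestPermuteAnnotation:
    universe = CaptureUniverse([iv(0, 10)])

    def test_zero_offset_is_identity(self):
        g = single_transcript_gene("g", [(2, 4)])
        fs = derive_features([g], kinds=("exon",))
        out = permute_annotation(fs, self.universe, offsets={"g.1": 0})
        assert [(f.interval.start, f.interval.end) for f in out] == [(2, 4)]

    def test_wrap_splits_into_two_pieces(self):
        g = single_transcript_gene("g", [(2, 4)])
        fs = derive_features([g], kinds=("exon",))
        out = permute_annotation(fs, self.universe, offsets={"g.1": 7})
        got = sorted((f.interval.start, f.interval.end) for f in out)
        assert got == [(0, 1), (9, 10)]

    def test_intra_transcript_gap_preserved_mod_wrap(self):
        big = CaptureUniverse([iv(0, 1000)])
        g = single_transcript_gene("g", [(100, 110), (120, 130)])
        fs = derive_features([g], kinds=("exon",))
        for delta in (0, 5, 500, 991):
            out = permute_annotation(fs, big, offsets={"g.1": delta})
            # unwrap: sort piece starts back into circular order from delta
            rel = sorted(((f.interval.start - 100 - delta) % 1000, f.interval.length) for f in out)
            spans = []
            for start, length in rel:
                spans.append((start, start + length))
            merged = []
            for s, e in spans:
                if merged and merged[-1][1] == s:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            assert merged == [(0, 10), (20, 30)]

    def test_total_feature_bp_conserved(self):
        big = CaptureUniverse([iv(0, 1000)])
        g = single_transcript_gene("g", [(100, 110), (120, 130), (400, 460)])
        fs = derive_features([g], kinds=("exon",))
        rng = np.random.default_rng(0)
        for _ in range(20):
            out = permute_annotation(fs, big, rng=rng)
            assert total_length([f.interval for f in out]) == 80

    def test_transcript_longer_than_region_errors(self):
        small = CaptureUniverse([iv(0, 50)])
        g = single_transcript_gene("g", [(0, 5), (45, 49)])  # span 49 ok
        permute_annotation(derive_features([g], kinds=("exon",)), small, offsets={"g.1": 1})
        g2 = single_transcript_gene("g2", [(0, 5), (45, 51)])  # span 51 > 50
        with pytest.raises(ValueError, match="longer than its capture region"):
            permute_annotation(
                derive_features([g2], kinds=("exon",)), small, offsets={"g2.1": 1}
            )


class TestPermutationTest:
    def test_saturated_feature_p_is_one(self):
        universe = CaptureUniverse([iv(0, 100)])
        g = single_transcript_gene("g", [(0, 100)])
        res = permutation_test([var(50)], [g], "exon", universe, n=200, seed=0)
        assert res.observed == 1
        assert res.p_empirical == 1.0
        assert res.expected_mean == 1.0

    def test_toy_rotation_exact_p_ccv_outside(self):
        """Single exon [0,2) in a 10-bp region, CCV at 5: observed 0, p 1."""
        universe = CaptureUniverse([iv(0, 10)])
        g = single_transcript_gene("g", [(0, 2)])
        res = permutation_test([var(5)], [g], "exon", universe, n=1000, seed=0)
        assert res.observed == 0 and res.p_empirical == 1.0

    def test_toy_rotation_exact_p_ccv_inside(self):
        """CCV placed in the exon: only 2 of 10 rotations cover it, p -> 2/10."""
        universe = CaptureUniverse([iv(0, 10)])
        g = single_transcript_gene("g", [(0, 2)])
        res = permutation_test([var(1)], [g], "exon", universe, n=50_000, seed=0)
        assert res.observed == 1
        assert res.p_empirical == pytest.approx(0.2, abs=3 * math.sqrt(0.2 * 0.8 / 50_000))

    def test_fast_path_matches_materialized_rotation_counts(self):
        """The offset-window fast path equals shift-then-intersect for every offset."""
        universe = CaptureUniverse([iv(0, 37)])
        g = single_transcript_gene("g", [(5, 9), (15, 18)])
        ccvs = [var(p) for p in (0, 4, 8, 16, 30)]
        fs = derive_features([g], kinds=("exon",))
        # exact distribution by materializing every rotation
        counts = []
        for d in range(37):
            shifted = permute_annotation(fs, universe, offsets={"g.1": d})
            _, k = ccvs_in_feature(ccvs, [f.interval for f in shifted])
            counts.append(k)
        exact_p = sum(1 for c in counts if c >= counts[0]) / 37
        res = permutation_test(ccvs, [g], "exon", universe, n=40_000, seed=5)
        assert res.observed == counts[0]
        se = math.sqrt(exact_p * (1 - exact_p) / 40_000)
        assert res.p_empirical == pytest.approx(exact_p, abs=4 * se)

    def test_replay_determinism_bit_for_bit(self, default_genome, default_signals):
        from mencrna.ccv import derive_ccvs

        _, genome = default_genome
        signals, _ = default_signals
        ccvs = [v for s in signals for v in derive_ccvs(s).ccvs]
        a = permutation_test(ccvs, genome.menc_genes, "exon", genome.universe, n=500, seed=9)
        b = permutation_test(ccvs, genome.menc_genes, "exon", genome.universe, n=500, seed=9)
        assert a == b

    def test_expected_mean_tracks_coverage_fraction(self):
        """Law of large numbers: mean overlap / n_ccv -> coverage fraction."""
        from mencrna.intervals import coverage_within

        universe = CaptureUniverse([iv(0, 5000)])
        g = single_transcript_gene("g", [(100, 300), (500, 800)])
        fs = derive_features([g], kinds=("exon",))
        _, frac = coverage_within(fs.intervals("exon"), universe)
        ccvs = [var(37 * i % 5000, vid=f"c{i}") for i in range(40)]
        means = []
        for seed in range(10):
            res = permutation_test(ccvs, [g], "exon", universe, n=4000, seed=seed)
            means.append(res.expected_mean / len(ccvs))
        grand = float(np.mean(means))
        se = float(np.std(means, ddof=1) / math.sqrt(len(means)))
        assert grand == pytest.approx(frac, abs=max(3 * se, 5e-3))

    def test_add_one_correction_floor(self):
        universe = CaptureUniverse([iv(0, 10)])
        g = single_transcript_gene("g", [(0, 2)])
        res = permutation_test([var(1)], [g], "exon", universe, n=1000, seed=0, add_one=True)
        assert res.p_empirical >= 1 / (res.n_permutations + 1)

    def test_invalid_feature_kind_rejected(self, toy_universe):
        g = single_transcript_gene("g", [(0, 2)])
        with pytest.raises(ValueError, match="feature kind"):
            permutation_test([var(1)], [g], "utr", toy_universe, n=200, seed=0)

    def test_small_n_warns(self, toy_universe):
        g = single_transcript_gene("g", [(0, 2)])
        with pytest.warns(UserWarning, match="permutations"):
            permutation_test([var(1)], [g], "exon", toy_universe, n=50, seed=0)
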