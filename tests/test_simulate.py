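"""Synthetic-data generators: determinism, structure, planted ground truth."""

import numpy as np
import pytest

from mencrna.capture_qc import fit_dose_response, lld
from mencrna.ccv import derive_ccvs
from mencrna.genes import derive_features
from mencrna.intervals import coverage_within
from mencrna.simulate import (
    SimConfig,
    simulate_ercc,
    simulate_expression,
    simulate_genome,
    simulate_loops,
    simulate_signals,
    simulate_tissue_panel,
)


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        a = simulate_genome(SimConfig(seed=5))
        b = simulate_genome(SimConfig(seed=5))
        assert a.manifest == b.manifest

    def test_genes_fit_inside_regions_and_are_multiexonic(self, default_genome):
        _, genome = default_genome
        for g in genome.genes:
            assert g.is_multi_exonic()
            ridx = genome.universe.region_index_at(g.chrom, g.start)
            assert ridx is not None
            region = genome.universe.regions[ridx]
            assert region.start <= g.start and g.end <= region.end

    def test_genes_do_not_overlap_each_other(self, default_genome):
        _, genome = default_genome
        by_chrom = {}
        for g in genome.genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_infeasible_packing_errors(self):
        with pytest.raises(ValueError, match="do not fit"):
            simulate_genome(SimConfig(seed=0, region_length=10_000, genes_per_region=50))

    def test_generated_genes_pass_capture_filters(self, default_genome):
        from mencrna.genes import filter_transcripts

        _, genome = default_genome
        kept, log = filter_transcripts(
            genome.menc_genes,
            genome.gene_max_fpkm,
            genome.isoform_max_fpkm,
            genome.universe,
            genome.coding_genes,
        )
        assert log == []
        assert len(kept) == len(genome.menc_genes)


class TestSimulateSignals:
    def test_derive_ccvs_recovers_planted_sets(self, default_genome, default_signals):
        signals, manifest = default_signals
        planted = {m["signal_id"]: m["ccv_ids"] for m in manifest["signals"]}
        for s in signals:
            assert sorted(derive_ccvs(s).variant_ids) == planted[s.signal_id]

    def test_null_exonic_fraction_matches_coverage(self):
        """enrichment 1: exonic CCV fraction ~ exon coverage (3-SE check)."""
        fracs, covs, total = [], [], 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, ccv_exon_enrichment=1.0)
            genome = simulate_genome(cfg)
            signals, _ = simulate_signals(cfg, genome)
            fs = derive_features(genome.menc_genes, kinds=("exon",))
            exon_ivs = fs.intervals("exon")
            _, cov = coverage_within(exon_ivs, genome.universe)
            ccvs = [v for s in signals for v in derive_ccvs(s).ccvs]
            from mencrna.ccv import ccvs_in_feature

            _, k = ccvs_in_feature(ccvs, exon_ivs)
            fracs.append(k)
            covs.append(cov * len(ccvs))
            total += len(ccvs)
        observed, expected = sum(fracs), sum(covs)
        se = np.sqrt(expected)  # Poisson-scale error on the expected count
        assert abs(observed - expected) <= 3 * se

    def test_enrichment_factor_three_inflates_overlap(self):
        """Odds multiplier 3 at ~5% coverage: overlap ratio ~ 3 (3-SE)."""
        from mencrna.ccv import ccvs_in_feature

        obs_tot, exp_tot, unif_tot = 0, 0.0, 0.0
        for seed in range(20):
            cfg = SimConfig(
                seed=seed, ccv_exon_enrichment=3.0, genes_per_region=25,
                exons_per_gene=(4, 8), exon_length=(300, 700),
                n_signals=20, ccvs_per_signal=(5, 10),
            )
            genome = simulate_genome(cfg)
            signals, _ = simulate_signals(cfg, genome)
            fs = derive_features(genome.menc_genes, kinds=("exon",))
            exon_ivs = fs.intervals("exon")
            _, cov = coverage_within(exon_ivs, genome.universe)
            ccvs = [v for s in signals for v in derive_ccvs(s).ccvs]
            _, k = ccvs_in_feature(ccvs, exon_ivs)
            obs_tot += k
            # expected under the odds model: e*c/(e*c + (1-c))
            e = 3.0
            exp_tot += len(ccvs) * (e * cov) / (e * cov + (1 - cov))
            unif_tot += len(ccvs) * cov
        assert abs(obs_tot - exp_tot) <= 3 * np.sqrt(exp_tot)
        # observed/uniform-expected ratio sits near the odds multiplier
        assert obs_tot / unif_tot > 2.0


class TestSimulateLoops:
    def test_planted_loops_join_promoter_and_ccv(self, default_genome, default_signals):
        cfg, genome = default_genome
        signals, _ = default_signals
        loops, manifest = simulate_loops(cfg, genome, signals)
        genes = {g.gene_id: g for g in genome.menc_genes}
        ccv_sets = {s.signal_id: derive_ccvs(s) for s in signals}
        by_id = {l.loop_id: l for l in loops}
        for planted in manifest["planted_loops"]:
            loop = by_id[planted["loop_id"]]
            g = genes[planted["gene_id"]]
            t = g.transcripts[0]
            prom = t.promoter("flank500")
            assert loop.anchor1.overlaps(prom) or loop.anchor2.overlaps(prom)
            cs = ccv_sets[planted["signal_id"]]
            hit = any(
                a.contains_point(v.chrom, v.pos)
                for v in cs.ccvs
                for a in (loop.anchor1, loop.anchor2)
            )
            assert hit


class TestSimulateExpression:
    def test_planted_effects_detectable_and_null_genes_quiet(self, default_genome, default_signals):
        cfg, genome = default_genome
        signals, _ = default_signals
        expr, geno, cn, manifest = simulate_expression(cfg, genome, signals)
        assert expr.shape == (len(genome.menc_genes), cfg.n_samples)
        assert ((geno.values >= 0) & (geno.values <= 2)).all()
        planted = manifest["planted_eqtl"]
        assert len(planted) == cfg.n_eqtl_genes
        # raw correlation between planted gene and its causal dosage is visible
        for gid, d in planted.items():
            r = np.corrcoef(expr.loc[gid], geno.loc[d["variant_id"]])[0, 1]
            assert abs(r) > 0.05

    def test_deterministic(self, default_genome, default_signals):
        cfg, genome = default_genome
        signals, _ = default_signals
        e1, g1, c1, m1 = simulate_expression(cfg, genome, signals)
        e2, g2, c2, m2 = simulate_expression(cfg, genome, signals)
        assert e1.equals(e2) and g1.equals(g2) and c1.equals(c2) and m1 == m2


class TestSimulateTissuePanel:
    def test_regimes_separate_in_tau(self):
        from mencrna.metrics import tau_table

        panel, manifest = simulate_tissue_panel(SimConfig(seed=0))
        taus = tau_table(panel)
        regimes = manifest["tau_regimes"]
        spec = [taus[g] for g, r in regimes.items() if r == "specific"]
        broad = [taus[g] for g, r in regimes.items() if r == "broad"]
        assert min(spec) > max(broad)
        assert all(t == 1.0 for t in spec)


class TestSimulateErcc:
    def test_planted_line_and_lld_recovered(self):
        cfg = SimConfig(seed=0)
        cap, non, manifest = simulate_ercc(cfg)
        fit_cap = fit_dose_response(cap)
        assert fit_cap.slope == pytest.approx(manifest["slope"], abs=1e-9)
        assert fit_cap.intercept == pytest.approx(manifest["intercept_captured"], abs=1e-9)
        assert lld(cap) == manifest["lld_captured"]
        assert lld(non) == manifest["lld_noncaptured"]
        assert lld(non) / lld(cap) > 100  # captured detects far lower input
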