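"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of a targeted RNA-capture
study around GWAS risk signals: 1.5-Mb capture regions, low-expression
multi-exonic gene models dominated by two-exon transcripts, risk signals
whose credible variants can be preferentially placed in exonic bp with a
tunable odds multiplier, chromatin loops joining promoters to
variant-bearing fragments, expression with additive genotype effects plus a
copy-number covariate and Gaussian noise, tissue panels with planted
specificity regimes, and ERCC spike-in tables with a planted dose-response
line. Every generator is deterministic under the config seed and records
its ground truth in a manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .capture_qc import DETECTION_FPKM, SpikeInTable
from .ccv import CCVSet, RiskSignal, Variant, derive_ccvs
from .genes import GeneModel, Transcript
from .intervals import CaptureUniverse, GenomicInterval
from .linkage import ChromatinLoop

__all__ = [
    "SimConfig",
    "SimGenome",
    "simulate_genome",
    "simulate_signals",
    "simulate_loops",
    "simulate_expression",
    "simulate_tissue_panel",
    "simulate_ercc",
    "manifest_links",
    "write_bundle",
]

CELL_LINES = ("B80T5", "MCF7", "T47D", "MDAMB231")

# stage-stream constants so each generator has an independent RNG stream
_S_GENOME, _S_SIGNALS, _S_LOOPS, _S_EXPR, _S_TISSUE, _S_ERCC = range(1, 7)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort."""

    seed: int = 0
    # genome
    n_regions: int = 10
    region_length: int = 1_500_000
    genes_per_region: int = 20
    coding_genes_per_region: int = 4
    exons_per_gene: tuple[int, int] = (2, 6)  # inclusive; two-exon models dominate real capture data
    exon_length: tuple[int, int] = (150, 600)
    intron_length: tuple[int, int] = (500, 5000)
    # signals
    n_signals: int = 15
    variants_per_signal: int = 30
    ccvs_per_signal: tuple[int, int] = (1, 10)
    lead_p_range: tuple[float, float] = (1e-12, 1e-8)
    ccv_exon_enrichment: float = 1.0
    # loops
    n_loops: int = 30
    loop_promoter_fraction: float = 0.5
    anchor_length: int = 4_000
    # expression / eQTL
    n_samples: int = 200
    n_eqtl_genes: int = 10
    eqtl_beta: float = 0.5
    noise_sd: float = 1.0
    copy_number_effect: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    # tissue panel
    tissue_count: int = 7
    n_tissue_genes: int = 200
    tissue_specificity: float = 0.5  # fraction of genes in the specific regime
    # ERCC
    n_ercc: int = 92
    ercc_slope: float = 1.0
    ercc_intercept_captured: float = 4.0
    ercc_lld_shift_log2: float = 8.23  # captured LLD ~300x lower
    ercc_noise_sd: float = 0.0

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.Generator(
            np.random.Philox(np.random.SeedSequence([int(self.seed), int(stream)]))
        )


@dataclass
class SimGenome:
    universe: CaptureUniverse
    genes: list[GeneModel]  # mencRNA + decoy protein_coding
    gene_max_fpkm: dict[str, float]
    isoform_max_fpkm: dict[str, float]
    manifest: dict = field(default_factory=dict)

    @property
    def menc_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "mencRNA"]

    @property
    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "protein_coding"]

    def region_of_gene(self, gene: GeneModel) -> int:
        idx = self.universe.region_index_at(gene.chrom, gene.transcripts[0].tss)
        assert idx is not None
        return idx


def _gene_structure(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[list[int], list[int]]:
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = rng.integers(
        cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_exons
    ).tolist()
    intron_lens = rng.integers(
        cfg.intron_length[0], cfg.intron_length[1] + 1, size=max(n_exons - 1, 0)
    ).tolist()
    return exon_lens, intron_lens


def simulate_genome(cfg: SimConfig) -> SimGenome:
    """Place multi-exonic gene models inside disjoint capture regions.

    One region per chromosome; mencRNA genes and decoy protein-coding genes
    are placed sequentially with random gaps so genes never overlap. Raises
    when the drawn gene structures cannot fit inside a region.
    """
    rng = cfg.rng(_S_GENOME)
    regions: list[GenomicInterval] = []
    genes: list[GeneModel] = []
    gene_max_fpkm: dict[str, float] = {}
    isoform_max_fpkm: dict[str, float] = {}
    manifest_genes = []
    for r in range(cfg.n_regions):
        chrom = f"chr{r + 1}"
        region_start = 10_000_000
        region = GenomicInterval(chrom, region_start, region_start + cfg.region_length)
        regions.append(region)
        n_total = cfg.genes_per_region + cfg.coding_genes_per_region
        structures = [_gene_structure(rng, cfg) for _ in range(n_total)]
        spans = [sum(e) + sum(i) for e, i in structures]
        # mark which placements are coding decoys, interleaved deterministically
        is_coding = np.zeros(n_total, dtype=bool)
        if cfg.coding_genes_per_region:
            step = max(n_total // cfg.coding_genes_per_region, 1)
            is_coding[[min((k + 1) * step - 1, n_total - 1) for k in range(cfg.coding_genes_per_region)]] = True
        slack = cfg.region_length - sum(spans) - 2_000 * (n_total + 1)
        if slack < 0:
            raise ValueError(
                f"region {chrom}: gene structures ({sum(spans)} bp) do not fit in "
                f"{cfg.region_length} bp"
            )
        gaps = rng.multinomial(slack, np.full(n_total + 1, 1.0 / (n_total + 1)))
        cursor = region.start
        menc_i = cod_i = 0
        for k in range(n_total):
            cursor += 2_000 + int(gaps[k])
            exon_lens, intron_lens = structures[k]
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = cursor
            for j, el in enumerate(exon_lens):
                exons.append(GenomicInterval(chrom, pos, pos + el, strand))
                pos += el
                if j < len(intron_lens):
                    pos += intron_lens[j]
            if is_coding[k]:
                gid = f"PC-{r:02d}{cod_i:03d}"
                biotype = "protein_coding"
                cod_i += 1
            else:
                gid = f"XLOC-{r:02d}{menc_i:03d}"
                biotype = "mencRNA"
                menc_i += 1
            tid = f"{gid}.1"
            genes.append(GeneModel(gid, [Transcript(tid, gid, tuple(exons))], biotype))
            fpkm = float(DETECTION_FPKM + rng.lognormal(0.0, 1.0))
            gene_max_fpkm[gid] = fpkm
            isoform_max_fpkm[tid] = fpkm
            manifest_genes.append(
                {
                    "gene_id": gid,
                    "biotype": biotype,
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [[e.start, e.end] for e in exons],
                    "max_fpkm": fpkm,
                }
            )
            cursor = pos
    universe = CaptureUniverse(regions)
    manifest = {
        "regions": [[iv.chrom, iv.start, iv.end] for iv in universe.regions],
        "genes": manifest_genes,
    }
    return SimGenome(universe, genes, gene_max_fpkm, isoform_max_fpkm, manifest)


def _interval_sampler(intervals: list[tuple[int, int]]):
    lens = np.array([e - s for s, e in intervals], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lens)])
    starts = np.array([s for s, _ in intervals], dtype=np.int64)

    def sample(rng: np.random.Generator) -> int:
        off = int(rng.integers(0, cum[-1]))
        k = int(np.searchsorted(cum, off, side="right")) - 1
        return int(starts[k] + (off - cum[k]))

    return sample, int(cum[-1])


def simulate_signals(
    cfg: SimConfig, genome: SimGenome
) -> tuple[list[RiskSignal], dict]:
    """Risk signals with planted CCV subsets and optional exonic placement bias.

    Per signal the lead p is log-uniform in ``lead_p_range``; planted CCVs
    get p in [p_lead, 100 p_lead] and non-CCVs p in [200 p_lead, 1e5 p_lead]
    so the two-orders rule recovers exactly the planted set. CCV positions
    are drawn with exonic-bp odds multiplied by ``ccv_exon_enrichment``
    (1 = uniform null); other variants are uniform over the region.
    """
    rng = cfg.rng(_S_SIGNALS)
    # per-region exon / non-exon samplers over mencRNA exon unions
    region_samplers = []
    for region in genome.universe.regions:
        exon_ivs: list[tuple[int, int]] = []
        for g in genome.menc_genes:
            if g.chrom != region.chrom:
                continue
            for iv in g.exon_union():
                s, e = max(iv.start, region.start), min(iv.end, region.end)
                if s < e:
                    exon_ivs.append((s, e))
        exon_ivs.sort()
        # complement within the region
        non_exon: list[tuple[int, int]] = []
        cursor = region.start
        for s, e in exon_ivs:
            if s > cursor:
                non_exon.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < region.end:
            non_exon.append((cursor, region.end))
        region_samplers.append(
            (
                _interval_sampler(exon_ivs) if exon_ivs else (None, 0),
                _interval_sampler(non_exon) if non_exon else (None, 0),
            )
        )

    signals: list[RiskSignal] = []
    manifest_signals = []
    lo, hi = np.log(cfg.lead_p_range[0]), np.log(cfg.lead_p_range[1])
    for i in range(cfg.n_signals):
        ridx = i % cfg.n_regions
        region = genome.universe.regions[ridx]
        (exon_sample, exon_bp), (non_sample, non_bp) = region_samplers[ridx]
        sid = f"signal{i:03d}"
        p_lead = float(np.exp(rng.uniform(lo, hi)))
        n_ccv = int(rng.integers(cfg.ccvs_per_signal[0], cfg.ccvs_per_signal[1] + 1))
        n_ccv = min(n_ccv, cfg.variants_per_signal)
        e = cfg.ccv_exon_enrichment
        p_exon = (e * exon_bp) / (e * exon_bp + non_bp) if exon_bp else 0.0
        variants = []
        ccv_ids = []
        for k in range(cfg.variants_per_signal):
            vid = f"{sid}_v{k:03d}"
            is_ccv = k < n_ccv
            if is_ccv:
                if k == 0:
                    p = p_lead
                else:
                    p = float(np.exp(rng.uniform(np.log(p_lead), np.log(100.0 * p_lead))))
                if rng.random() < p_exon:
                    pos = exon_sample(rng)
                else:
                    pos = non_sample(rng)
                ccv_ids.append(vid)
            else:
                p = float(
                    np.exp(
                        rng.uniform(np.log(200.0 * p_lead), np.log(min(1.0, 1e5 * p_lead)))
                    )
                )
                # uniform over the whole region
                off = int(rng.integers(0, region.length))
                pos = region.start + off
            variants.append(Variant(vid, region.chrom, pos, p))
        signals.append(RiskSignal(sid, f"region{ridx:02d}", variants))
        manifest_signals.append(
            {
                "signal_id": sid,
                "region_index": ridx,
                "lead": f"{sid}_v000",
                "p_lead": p_lead,
                "ccv_ids": sorted(ccv_ids),
            }
        )
    manifest = {"signals": manifest_signals}
    # cross-check: the two-orders rule must recover exactly the planted sets
    for sig, ms in zip(signals, manifest_signals):
        got = sorted(derive_ccvs(sig).variant_ids)
        assert got == ms["ccv_ids"], f"planted CCV set mismatch for {sig.signal_id}"
    return signals, manifest


def simulate_loops(
    cfg: SimConfig, genome: SimGenome, signals: Sequence[RiskSignal]
) -> tuple[list[ChromatinLoop], dict]:
    """Chromatin loops: a planted fraction joins a mencRNA promoter anchor to
    a CCV-bearing anchor; the rest are decoy anchor pairs."""
    rng = cfg.rng(_S_LOOPS)
    ccv_sets = {s.signal_id: derive_ccvs(s) for s in signals}
    signals_by_region: dict[int, list[RiskSignal]] = {}
    for s in signals:
        ridx = genome.universe.region_index_at(
            s.variants[0].chrom, s.variants[0].pos
        )
        assert ridx is not None
        signals_by_region.setdefault(ridx, []).append(s)

    loops: list[ChromatinLoop] = []
    planted = []
    n_planted = int(round(cfg.n_loops * cfg.loop_promoter_fraction))
    menc = genome.menc_genes
    half = cfg.anchor_length // 2
    li = 0
    attempts = 0
    while len(planted) < n_planted and attempts < 20 * n_planted:
        attempts += 1
        g = menc[int(rng.integers(0, len(menc)))]
        ridx = genome.region_of_gene(g)
        region = genome.universe.regions[ridx]
        sigs = signals_by_region.get(ridx, [])
        if not sigs:
            continue
        s = sigs[int(rng.integers(0, len(sigs)))]
        ccvs = ccv_sets[s.signal_id].ccvs
        v = ccvs[int(rng.integers(0, len(ccvs)))]
        tss = g.transcripts[0].tss
        a1 = GenomicInterval(
            g.chrom, max(tss - half, region.start), min(tss + half, region.end)
        )
        a2 = GenomicInterval(
            g.chrom, max(v.pos - half, region.start), min(v.pos + half + 1, region.end)
        )
        if a1.overlaps(a2):
            continue  # promoter and CCV too close; loop route would be ambiguous
        cell = CELL_LINES[li % len(CELL_LINES)]
        loops.append(ChromatinLoop(a1, a2, cell_line=cell, loop_id=f"loop{li:03d}"))
        planted.append(
            {"gene_id": g.gene_id, "signal_id": s.signal_id, "loop_id": f"loop{li:03d}"}
        )
        li += 1
    # decoys: random anchor pairs within a region
    while li < cfg.n_loops:
        ridx = int(rng.integers(0, cfg.n_regions))
        region = genome.universe.regions[ridx]
        s1 = region.start + int(rng.integers(0, region.length - cfg.anchor_length))
        s2 = region.start + int(rng.integers(0, region.length - cfg.anchor_length))
        a1 = GenomicInterval(region.chrom, s1, s1 + cfg.anchor_length)
        a2 = GenomicInterval(region.chrom, s2, s2 + cfg.anchor_length)
        if a1.overlaps(a2):
            continue
        cell = CELL_LINES[li % len(CELL_LINES)]
        loops.append(ChromatinLoop(a1, a2, cell_line=cell, loop_id=f"loop{li:03d}"))
        li += 1
    return loops, {"planted_loops": planted}


def simulate_expression(
    cfg: SimConfig, genome: SimGenome, signals: Sequence[RiskSignal]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Expression, genotype dosages and copy number with planted cis effects.

    Dosages are binomial(2, MAF) with MAF uniform in ``maf_range``.
    Expression (already on the log-normalized analysis scale) is
    ``baseline + beta * dosage(causal CCV) + gamma * copy_number + noise``
    for planted eQTL genes, and ``baseline + gamma * copy_number + noise``
    otherwise. Returns ``(expression, genotypes, copy_number, manifest)``.
    """
    rng = cfg.rng(_S_EXPR)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    variants = [v for s in signals for v in s.variants]
    vids = [v.variant_id for v in variants]
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=len(vids))
    dosage = rng.binomial(2, mafs[:, None], size=(len(vids), cfg.n_samples)).astype(float)
    genotypes = pd.DataFrame(dosage, index=vids, columns=samples)

    menc = genome.menc_genes
    gene_ids = [g.gene_id for g in menc]
    copy_number = pd.DataFrame(
        rng.normal(2.0, 0.3, size=(len(gene_ids), cfg.n_samples)),
        index=gene_ids,
        columns=samples,
    )

    # eligible planted genes need >= 1 CCV-bearing signal in their region
    ccv_by_region: dict[int, list[Variant]] = {}
    for s in signals:
        cs = derive_ccvs(s)
        ridx = genome.universe.region_index_at(s.variants[0].chrom, s.variants[0].pos)
        assert ridx is not None
        ccv_by_region.setdefault(ridx, []).extend(cs.ccvs)
    eligible = [g for g in menc if ccv_by_region.get(genome.region_of_gene(g))]
    n_plant = min(cfg.n_eqtl_genes, len(eligible)) if cfg.eqtl_beta != 0 else 0
    plant_idx = (
        rng.choice(len(eligible), size=n_plant, replace=False) if n_plant else []
    )
    planted: dict[str, dict] = {}
    for gi in sorted(int(i) for i in plant_idx):
        g = eligible[gi]
        pool = ccv_by_region[genome.region_of_gene(g)]
        v = pool[int(rng.integers(0, len(pool)))]
        planted[g.gene_id] = {"variant_id": v.variant_id, "beta": cfg.eqtl_beta}

    expr = np.empty((len(gene_ids), cfg.n_samples))
    for i, g in enumerate(menc):
        baseline = rng.normal(3.0, 1.0)
        y = baseline + cfg.copy_number_effect * copy_number.iloc[i].to_numpy()
        if g.gene_id in planted:
            y = y + cfg.eqtl_beta * genotypes.loc[planted[g.gene_id]["variant_id"]].to_numpy()
        y = y + rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples)
        expr[i] = y
    expression = pd.DataFrame(expr, index=gene_ids, columns=samples)
    manifest = {"planted_eqtl": planted, "n_samples": cfg.n_samples}
    return expression, genotypes, copy_number, manifest


def cis_tests(
    genome: SimGenome, signals: Sequence[RiskSignal]
) -> dict[str, list[str]]:
    """gene -> variant ids sharing the gene's capture region (the cis set)."""
    by_region: dict[int, list[str]] = {}
    for s in signals:
        for v in s.variants:
            ridx = genome.universe.region_index_at(v.chrom, v.pos)
            if ridx is not None:
                by_region.setdefault(ridx, []).append(v.variant_id)
    tests = {}
    for g in genome.menc_genes:
        vids = by_region.get(genome.region_of_gene(g), [])
        if vids:
            tests[g.gene_id] = sorted(vids)
    return tests


def simulate_coexpression(
    cfg: SimConfig,
    n_pairs: int = 50,
    looped_fraction: float = 0.5,
    shared_r: float = 0.6,
) -> tuple[pd.DataFrame, list[GeneModel], list[GeneModel], list[ChromatinLoop], dict]:
    """mencRNA / protein-coding gene pairs for the looped-pair comparison.

    Each pair sits 200 kb apart (inside the 1-Mb window), isolated 3 Mb from
    the next pair. A ``looped_fraction`` of pairs is joined by a promoter
    loop and shares a latent expression factor giving correlation
    ``shared_r``; the rest are independent. Expression is on the
    log-normalized scale. Returns
    ``(expression, menc_genes, coding_genes, loops, manifest)``.
    """
    _S_COEXPR = 7
    rng = cfg.rng(_S_COEXPR)
    n_looped = int(round(n_pairs * looped_fraction))
    shared_r = max(shared_r, 0.0)
    lam = math.sqrt(shared_r)
    menc: list[GeneModel] = []
    coding: list[GeneModel] = []
    loops: list[ChromatinLoop] = []
    rows, idx, pair_rows = [], [], []
    for i in range(n_pairs):
        a_tss = 3_000_000 * (i + 1)
        b_tss = a_tss + 200_000
        ga = GeneModel(
            f"nc{i:03d}",
            [
                Transcript(
                    f"nc{i:03d}.1",
                    f"nc{i:03d}",
                    (
                        GenomicInterval("chr1", a_tss, a_tss + 200, "+"),
                        GenomicInterval("chr1", a_tss + 1000, a_tss + 1200, "+"),
                    ),
                )
            ],
            "mencRNA",
        )
        gb = GeneModel(
            f"pc{i:03d}",
            [
                Transcript(
                    f"pc{i:03d}.1",
                    f"pc{i:03d}",
                    (
                        GenomicInterval("chr1", b_tss, b_tss + 200, "+"),
                        GenomicInterval("chr1", b_tss + 1000, b_tss + 1200, "+"),
                    ),
                )
            ],
            "protein_coding",
        )
        menc.append(ga)
        coding.append(gb)
        looped = i < n_looped
        if looped:
            loops.append(
                ChromatinLoop(
                    GenomicInterval("chr1", a_tss - 400, a_tss + 400),
                    GenomicInterval("chr1", b_tss - 400, b_tss + 400),
                    cell_line=CELL_LINES[i % len(CELL_LINES)],
                    loop_id=f"coloop{i:03d}",
                )
            )
            shared = rng.normal(size=cfg.n_samples)
            xa = lam * shared + math.sqrt(1 - lam**2) * rng.normal(size=cfg.n_samples)
            xb = lam * shared + math.sqrt(1 - lam**2) * rng.normal(size=cfg.n_samples)
        else:
            xa = rng.normal(size=cfg.n_samples)
            xb = rng.normal(size=cfg.n_samples)
        rows += [xa, xb]
        idx += [ga.gene_id, gb.gene_id]
        pair_rows.append(
            {"menc": ga.gene_id, "coding": gb.gene_id, "looped": looped}
        )
    expr = pd.DataFrame(
        rows, index=idx, columns=[f"S{j:04d}" for j in range(cfg.n_samples)]
    )
    manifest = {"pairs": pair_rows, "shared_r": shared_r}
    return expr, menc, coding, loops, manifest


def simulate_tissue_panel(cfg: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Genes x tissues mean-FPKM panel with planted specificity regimes.

    Specific-regime genes express in a single tissue; broad-regime genes
    express everywhere with mild lognormal variation.
    """
    rng = cfg.rng(_S_TISSUE)
    n_spec = int(round(cfg.n_tissue_genes * cfg.tissue_specificity))
    rows = []
    regimes = {}
    tissues = [f"tissue{t}" for t in range(cfg.tissue_count)]
    for i in range(cfg.n_tissue_genes):
        gid = f"TG{i:04d}"
        if i < n_spec:
            home = int(rng.integers(0, cfg.tissue_count))
            x = np.zeros(cfg.tissue_count)
            x[home] = rng.lognormal(3.0, 0.5)
            regimes[gid] = "specific"
        else:
            x = rng.lognormal(3.0, 0.2, size=cfg.tissue_count)
            regimes[gid] = "broad"
        rows.append(x)
    panel = pd.DataFrame(rows, index=[f"TG{i:04d}" for i in range(cfg.n_tissue_genes)],
                         columns=tissues)
    return panel, {"tau_regimes": regimes}


def simulate_ercc(cfg: SimConfig) -> tuple[SpikeInTable, SpikeInTable, dict]:
    """Captured / non-captured spike-in tables from a planted dose-response.

    Concentrations follow a log2 ladder; FPKM is exactly
    ``2 ** (intercept + slope * log2(conc))`` plus optional Gaussian noise on
    the log2 scale. The captured library's intercept sits
    ``ercc_lld_shift_log2`` above the non-captured one, shifting the
    detection boundary accordingly.
    """
    rng = cfg.rng(_S_ERCC)
    n_levels = max(cfg.n_ercc // 4, 1)
    levels = np.logspace(-10, 12, num=n_levels, base=2.0)
    conc = np.repeat(levels, 4)[: cfg.n_ercc]
    if conc.size < cfg.n_ercc:
        conc = np.concatenate([conc, np.full(cfg.n_ercc - conc.size, levels[-1])])
    names = [f"ERCC-{i:05d}" for i in range(cfg.n_ercc)]

    def table(intercept: float, library_id: str, captured: bool) -> SpikeInTable:
        log2_fpkm = intercept + cfg.ercc_slope * np.log2(conc)
        if cfg.ercc_noise_sd > 0:
            log2_fpkm = log2_fpkm + rng.normal(0.0, cfg.ercc_noise_sd, size=conc.size)
        df = pd.DataFrame(
            {"transcript": names, "concentration": conc, "fpkm": 2.0**log2_fpkm}
        )
        return SpikeInTable(df, library_id=library_id, captured=captured)

    int_cap = cfg.ercc_intercept_captured
    int_non = cfg.ercc_intercept_captured - cfg.ercc_lld_shift_log2
    cap = table(int_cap, "captured", True)
    non = table(int_non, "noncaptured", False)

    def planted_lld(intercept: float) -> float:
        fpkm = 2.0 ** (intercept + cfg.ercc_slope * np.log2(conc))
        det = conc[fpkm >= DETECTION_FPKM]
        return float(det.min()) if det.size else float("nan")

    manifest = {
        "slope": cfg.ercc_slope,
        "intercept_captured": int_cap,
        "intercept_noncaptured": int_non,
        "fold_at_any_conc": 2.0**cfg.ercc_lld_shift_log2,
        "lld_captured": planted_lld(int_cap),
        "lld_noncaptured": planted_lld(int_non),
    }
    return cap, non, manifest


def manifest_links(
    genome: SimGenome,
    signals: Sequence[RiskSignal],
    loops: Sequence[ChromatinLoop],
) -> list[dict]:
    """Ground-truth (gene, signal, route) triples by direct geometry scan.

    Deliberately plain per-variant loops (no calls into the linkage module)
    so the end-to-end recovery test checks two independent implementations
    of the route rules against each other. Promoters are the loop-stage
    definition: TSS ±500 bp.
    """
    triples: set[tuple[str, str, str]] = set()
    ccv_sets = [derive_ccvs(s) for s in signals]
    for g in genome.menc_genes:
        t = g.transcripts[0]
        exons = [(e.start, e.end) for tr in g.transcripts for e in tr.exons]
        tss = t.tss
        prom = (max(tss - 500, 0), tss + 501)
        for cs in ccv_sets:
            for v in cs.ccvs:
                if v.chrom != g.chrom:
                    continue
                if any(s <= v.pos < e for s, e in exons):
                    triples.add((g.gene_id, cs.signal_id, "exon"))
                if prom[0] <= v.pos < prom[1]:
                    triples.add((g.gene_id, cs.signal_id, "promoter"))
        for loop in loops:
            for pa, ca in ((loop.anchor1, loop.anchor2), (loop.anchor2, loop.anchor1)):
                if pa.chrom != g.chrom:
                    continue
                if not (pa.start < prom[1] and prom[0] < pa.end):
                    continue
                for cs in ccv_sets:
                    if any(
                        v.chrom == ca.chrom and ca.start <= v.pos < ca.end
                        for v in cs.ccvs
                    ):
                        triples.add((g.gene_id, cs.signal_id, "loop"))
    return [
        {"gene_id": g, "signal_id": s, "route": r}
        for g, s, r in sorted(triples)
    ]


def write_bundle(cfg: SimConfig, out_dir: str) -> dict:
    """Generate and write the complete synthetic input bundle + manifest."""
    import os

    from . import io as mio

    os.makedirs(out_dir, exist_ok=True)
    genome = simulate_genome(cfg)
    signals, sig_manifest = simulate_signals(cfg, genome)
    loops, loop_manifest = simulate_loops(cfg, genome, signals)
    expression, genotypes, copy_number, expr_manifest = simulate_expression(
        cfg, genome, signals
    )
    panel, tissue_manifest = simulate_tissue_panel(cfg)
    ercc_cap, ercc_non, ercc_manifest = simulate_ercc(cfg)

    mio.write_bed(genome.universe.regions, os.path.join(out_dir, "universe.bed"))
    mio.write_gtf(genome.genes, os.path.join(out_dir, "genes.gtf"))
    mio.write_variants(signals, os.path.join(out_dir, "variants.tsv"))
    mio.write_bedpe(loops, os.path.join(out_dir, "loops.bedpe"))
    mio.write_matrix_tsv(expression, os.path.join(out_dir, "expression.tsv"))
    mio.write_matrix_tsv(genotypes, os.path.join(out_dir, "genotypes.tsv"))
    mio.write_matrix_tsv(copy_number, os.path.join(out_dir, "copy_number.tsv"))
    mio.write_matrix_tsv(panel, os.path.join(out_dir, "tissue_panel.tsv"))
    mio.write_expression_mapping(
        genome.gene_max_fpkm, os.path.join(out_dir, "gene_max_fpkm.tsv"), "gene_id"
    )
    mio.write_expression_mapping(
        genome.isoform_max_fpkm,
        os.path.join(out_dir, "isoform_max_fpkm.tsv"),
        "transcript_id",
    )
    mio.write_spikein_tsv(ercc_cap, os.path.join(out_dir, "ercc_captured.tsv"))
    mio.write_spikein_tsv(ercc_non, os.path.join(out_dir, "ercc_noncaptured.tsv"))

    manifest = {
        "config": asdict(cfg),
        "genome": genome.manifest,
        **sig_manifest,
        **loop_manifest,
        "expression": expr_manifest,
        **tissue_manifest,
        "ercc": ercc_manifest,
        "links": manifest_links(genome, signals, loops),
        "cis_tests": cis_tests(genome, signals),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
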