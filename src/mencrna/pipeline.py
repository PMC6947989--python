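"""End-to-end orchestration: config, stage sequencing, output layout.

Stage order mirrors the analysis: filter the captured annotation, derive
CCV sets, run the feature-restricted enrichment, link CCVs to candidate
target genes by the three routes, scan for eQTLs with the signal-overlap
rule, compute expression metrics, and summarize capture QC. Every output
is a deterministic text table; a run manifest records the seed and a hash
of the configuration so reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .capture_qc import (
    capture_fold_enrichment,
    fit_dose_response,
    lld,
    uld,
)
from .ccv import derive_ccvs
from .enrichment import permutation_test
from .eqtl import FDR_THRESHOLD, eqtl_signal_overlap, fit_eqtl, normalize_expression
from .genes import filter_transcripts
from .linkage import link_exonic, link_loops, link_promoter, multi_signal_targets
from .metrics import tau_table

__all__ = ["RunConfig", "run_end_to_end", "StageError"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths, toggles and thresholds for one pipeline run."""

    universe_bed: str
    gtf: str
    variants_tsv: str
    out_dir: str
    loops_bedpe: str | None = None
    expression_tsv: str | None = None
    genotypes_tsv: str | None = None
    copy_number_tsv: str | None = None
    tissue_panel_tsv: str | None = None
    gene_max_fpkm_tsv: str | None = None
    isoform_max_fpkm_tsv: str | None = None
    ercc_captured_tsv: str | None = None
    ercc_noncaptured_tsv: str | None = None
    cis_tests_json: str | None = None
    stages: list[str] = field(
        default_factory=lambda: ["filter", "ccv", "enrich", "link", "eqtl", "metrics", "qc"]
    )
    n_permutations: int = 100_000
    seed: int = 0
    enrichment_promoter_mode: str = "upstream500"
    linkage_promoter_mode: str = "flank500"
    gene_min_fpkm: float = 0.5
    isoform_min_fpkm: float = 0.01
    fdr: float = FDR_THRESHOLD
    correlation_window: int = 1_000_000
    normalize: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # analysis identity, not output location
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def require(self, attr: str, stage: str) -> str:
        path = getattr(self, attr)
        if path is None:
            raise StageError(f"stage {stage!r}: config field {attr!r} is not set")
        if not os.path.exists(path):
            raise StageError(f"stage {stage!r}: input file not found: {path}")
        return path


def run_end_to_end(cfg: RunConfig) -> dict:
    """Run all enabled stages; returns a summary dict (also written as JSON).

    A stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages are retained.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash()}

    universe = mio.read_universe(cfg.require("universe_bed", "load"))
    genes = mio.read_gtf(cfg.require("gtf", "load"))
    signals = mio.read_variants(cfg.require("variants_tsv", "load"))

    # --- filter ------------------------------------------------------------
    if "filter" in cfg.stages and cfg.gene_max_fpkm_tsv is not None:
        try:
            gene_fpkm = mio.read_expression_mapping(cfg.require("gene_max_fpkm_tsv", "filter"))
            iso_fpkm = (
                mio.read_expression_mapping(cfg.require("isoform_max_fpkm_tsv", "filter"))
                if cfg.isoform_max_fpkm_tsv
                else {}
            )
            coding = [g for g in genes if g.biotype == "protein_coding"]
            candidates = [g for g in genes if g.biotype != "protein_coding"]
            kept, log = filter_transcripts(
                candidates,
                gene_fpkm,
                iso_fpkm,
                universe,
                coding,
                gene_min_fpkm=cfg.gene_min_fpkm,
                isoform_min_fpkm=cfg.isoform_min_fpkm,
            )
            mio.write_removal_log(log, os.path.join(cfg.out_dir, "removals.tsv"))
            mio.write_gtf(kept + coding, os.path.join(cfg.out_dir, "filtered.gtf"))
            genes = kept + coding
            summary["filter"] = {"retained": len(kept), "removed": len(log)}
        except StageError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(f"stage 'filter' failed: {exc}") from exc

    menc = [g for g in genes if g.biotype == "mencRNA"] or [
        g for g in genes if g.biotype != "protein_coding"
    ]

    # --- ccv ---------------------------------------------------------------
    ccv_sets = [derive_ccvs(s) for s in signals]
    mio.write_ccv_bed(ccv_sets, os.path.join(cfg.out_dir, "ccvs.bed"))
    summary["ccv"] = {
        "n_signals": len(ccv_sets),
        "n_ccvs": sum(len(c.ccvs) for c in ccv_sets),
    }

    all_ccvs = [v for cs in ccv_sets for v in cs.ccvs]

    # --- enrichment --------------------------------------------------------
    if "enrich" in cfg.stages:
        try:
            rows = []
            for kind in ("exon", "intron", "promoter"):
                res = permutation_test(
                    all_ccvs,
                    menc,
                    kind,
                    universe,
                    n=cfg.n_permutations,
                    seed=cfg.seed,
                    promoter_mode=cfg.enrichment_promoter_mode,  # type: ignore[arg-type]
                )
                rows.append(res.as_dict())
            enr = pd.DataFrame(rows)
            enr.to_csv(os.path.join(cfg.out_dir, "enrichment.tsv"), sep="\t", index=False)
            with open(os.path.join(cfg.out_dir, "enrichment.json"), "w") as fh:
                json.dump(rows, fh, indent=1, sort_keys=True)
            summary["enrich"] = {r["feature"]: r["p_empirical"] for r in rows}
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage 'enrich' failed: {exc}") from exc

    # --- linkage -----------------------------------------------------------
    records = []
    if "link" in cfg.stages:
        try:
            records = link_exonic(ccv_sets, menc) + link_promoter(
                ccv_sets, menc, promoter_mode=cfg.linkage_promoter_mode  # type: ignore[arg-type]
            )
            if cfg.loops_bedpe is not None:
                loops = mio.read_bedpe(cfg.require("loops_bedpe", "link"))
                records += link_loops(
                    ccv_sets, menc, loops,
                    promoter_mode=cfg.linkage_promoter_mode,  # type: ignore[arg-type]
                )
            mio.write_linkage_tsv(records, os.path.join(cfg.out_dir, "linkage.tsv"))
            targets = multi_signal_targets(records)
            pd.DataFrame(
                [
                    {
                        "gene_id": t.gene_id,
                        "signals": ",".join(t.signal_ids),
                        "routes": ",".join(t.routes),
                    }
                    for t in targets
                ],
                columns=["gene_id", "signals", "routes"],
            ).to_csv(os.path.join(cfg.out_dir, "multi_signal_targets.tsv"), sep="\t", index=False)
            summary["link"] = {
                "n_records": len(records),
                "n_multi_signal_genes": len(targets),
            }
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage 'link' failed: {exc}") from exc

    # --- eqtl --------------------------------------------------------------
    if "eqtl" in cfg.stages and cfg.expression_tsv is not None:
        try:
            expression = mio.read_matrix_tsv(cfg.require("expression_tsv", "eqtl"))
            genotypes = mio.read_matrix_tsv(cfg.require("genotypes_tsv", "eqtl"))
            copy_number = (
                mio.read_matrix_tsv(cfg.require("copy_number_tsv", "eqtl"))
                if cfg.copy_number_tsv
                else None
            )
            if cfg.normalize:
                expression = normalize_expression(expression, log=False)
            if cfg.cis_tests_json is not None:
                with open(cfg.require("cis_tests_json", "eqtl")) as fh:
                    tests = json.load(fh)
            else:
                tests = _cis_tests_from_universe(menc, signals, universe)
            results = fit_eqtl(genotypes, expression, tests, copy_number=copy_number)
            df = pd.DataFrame(
                [
                    {
                        "gene_id": r.gene_id,
                        "variant_id": r.variant_id,
                        "beta": r.beta,
                        "se": r.se,
                        "p": r.p,
                        "q": r.q,
                    }
                    for r in results
                ]
            )
            df.to_csv(os.path.join(cfg.out_dir, "eqtl.tsv"), sep="\t", index=False)
            by_gene: dict[str, list] = {}
            for r in results:
                by_gene.setdefault(r.gene_id, []).append(r)
            verdict_rows = []
            for gene_id in sorted(by_gene):
                best_q = min(r.q for r in by_gene[gene_id])
                for cs in ccv_sets:
                    overlaps, top, best_ccv = eqtl_signal_overlap(by_gene[gene_id], cs)
                    verdict_rows.append(
                        {
                            "gene_id": gene_id,
                            "signal_id": cs.signal_id,
                            "significant": bool(best_q < cfg.fdr),
                            "overlaps_signal": overlaps,
                            "top_variant": top,
                            "best_ccv": best_ccv if best_ccv is not None else ".",
                        }
                    )
            pd.DataFrame(verdict_rows).to_csv(
                os.path.join(cfg.out_dir, "eqtl_overlap.tsv"), sep="\t", index=False
            )
            n_sig = sum(
                1
                for gene_id in by_gene
                if min(r.q for r in by_gene[gene_id]) < cfg.fdr
            )
            summary["eqtl"] = {"n_tests": len(results), "n_egenes": n_sig}
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage 'eqtl' failed: {exc}") from exc

    # --- metrics -----------------------------------------------------------
    if "metrics" in cfg.stages and cfg.tissue_panel_tsv is not None:
        try:
            panel = mio.read_matrix_tsv(cfg.require("tissue_panel_tsv", "metrics"))
            taus = tau_table(panel)
            taus.to_frame().to_csv(os.path.join(cfg.out_dir, "tau.tsv"), sep="\t")
            summary["metrics"] = {"median_tau": float(np.nanmedian(taus.to_numpy()))}
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage 'metrics' failed: {exc}") from exc

    # --- capture QC --------------------------------------------------------
    if "qc" in cfg.stages and cfg.ercc_captured_tsv is not None:
        try:
            cap = mio.read_spikein_tsv(
                cfg.require("ercc_captured_tsv", "qc"), "captured", True
            )
            rows = []
            cap_fit = fit_dose_response(cap)
            rows.append(_qc_row(cap, cap_fit))
            if cfg.ercc_noncaptured_tsv is not None:
                non = mio.read_spikein_tsv(
                    cfg.require("ercc_noncaptured_tsv", "qc"), "noncaptured", False
                )
                non_fit = fit_dose_response(non)
                rows.append(_qc_row(non, non_fit))
                shared = sorted(
                    set(cap.detected()["concentration"])
                    & set(non.detected()["concentration"])
                )
                if shared:
                    geo = float(np.exp(np.mean(np.log(shared))))
                    summary["qc"] = {
                        "fold_enrichment_geomean": capture_fold_enrichment(
                            cap_fit, non_fit, geo
                        ),
                        "fold_enrichment_min_conc": capture_fold_enrichment(
                            cap_fit, non_fit, shared[0]
                        ),
                        "fold_enrichment_max_conc": capture_fold_enrichment(
                            cap_fit, non_fit, shared[-1]
                        ),
                        "lld_ratio": lld(non) / lld(cap),
                    }
            pd.DataFrame(rows).to_csv(
                os.path.join(cfg.out_dir, "capture_qc.tsv"), sep="\t", index=False
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage 'qc' failed: {exc}") from exc

    with open(os.path.join(cfg.out_dir, "run_manifest.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _qc_row(table, fit) -> dict:
    return {
        "library": fit.library_id,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r2": fit.r2,
        "n_detected": fit.n_detected,
        "lld": lld(table),
        "uld": uld(table),
    }


def _cis_tests_from_universe(menc, signals, universe) -> dict[str, list[str]]:
    by_region: dict[int, list[str]] = {}
    for s in signals:
        for v in s.variants:
            ridx = universe.region_index_at(v.chrom, v.pos)
            if ridx is not None:
                by_region.setdefault(ridx, []).append(v.variant_id)
    tests = {}
    for g in menc:
        ridx = universe.region_index_at(g.chrom, g.transcripts[0].tss)
        if ridx is not None and by_region.get(ridx):
            tests[g.gene_id] = sorted(by_region[ridx])
    return tests
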