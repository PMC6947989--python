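"""CCV-to-gene linkage by the three evidence routes.

A mencRNA gene is a candidate target of a risk signal when a CCV of the
signal falls (1) in a gene exon, (2) in a gene promoter, or (3) in one
anchor of a chromatin loop whose other anchor overlaps a gene promoter.
Genes supported by CCVs from two or more distinct signals are reported as
multi-signal targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .ccv import CCVSet, Variant, ccvs_in_feature
from .genes import FeatureSet, GeneModel, PromoterMode, derive_features
from .intervals import GenomicInterval

__all__ = [
    "ChromatinLoop",
    "LinkageRecord",
    "link_exonic",
    "link_promoter",
    "link_loops",
    "multi_signal_targets",
]


@dataclass(frozen=True)
class ChromatinLoop:
    """A promoter-capture chromatin interaction between two anchors."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    cell_line: str
    loop_id: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.anchor1 == self.anchor2:
            raise ValueError("loop anchors are identical")


@dataclass(frozen=True)
class LinkageRecord:
    """One (gene, signal) link with its route and supporting evidence."""

    gene_id: str
    signal_id: str
    route: str  # {exon, promoter, loop}
    variant_ids: tuple[str, ...]
    loop_id: str = ""
    cell_line: str = ""


def _link_by_feature(
    ccv_sets: Sequence[CCVSet],
    features: FeatureSet,
    kind: str,
    route: str,
) -> list[LinkageRecord]:
    # per-gene feature intervals
    by_gene: dict[str, list[GenomicInterval]] = {}
    for f in features.kind(kind):
        by_gene.setdefault(f.gene_id, []).append(f.interval)
    records = []
    for cs in ccv_sets:
        for gene_id in sorted(by_gene):
            ids, k = ccvs_in_feature(cs.ccvs, by_gene[gene_id])
            if k:
                records.append(
                    LinkageRecord(gene_id, cs.signal_id, route, tuple(ids))
                )
    return records


def link_exonic(
    ccv_sets: Sequence[CCVSet], genes: Sequence[GeneModel]
) -> list[LinkageRecord]:
    """(gene, signal) pairs with >= 1 CCV inside a gene exon."""
    fs = derive_features(genes)
    return _link_by_feature(ccv_sets, fs, "exon", "exon")


def link_promoter(
    ccv_sets: Sequence[CCVSet],
    genes: Sequence[GeneModel],
    promoter_mode: PromoterMode = "flank500",
) -> list[LinkageRecord]:
    """(gene, signal) pairs with >= 1 CCV inside a gene promoter."""
    fs = derive_features(genes, promoter_mode=promoter_mode)
    return _link_by_feature(ccv_sets, fs, "promoter", "promoter")


def link_loops(
    ccv_sets: Sequence[CCVSet],
    genes: Sequence[GeneModel],
    loops: Sequence[ChromatinLoop],
    promoter_mode: PromoterMode = "flank500",
) -> list[LinkageRecord]:
    """(gene, signal) pairs joined by a chromatin loop.

    A record fires when one loop anchor overlaps (>= 1 bp) a gene promoter
    (±500 bp around the TSS by default) and the other anchor contains >= 1
    CCV of the signal; symmetric in anchor order. One record per
    (gene, signal, loop, cell line); count-level dedup happens in
    :func:`multi_signal_targets`.
    """
    fs = derive_features(genes, promoter_mode=promoter_mode)
    prom_by_gene: dict[str, list[GenomicInterval]] = {}
    for f in fs.promoters:
        prom_by_gene.setdefault(f.gene_id, []).append(f.interval)

    records = []
    for li, loop in enumerate(loops):
        loop_id = loop.loop_id or f"loop{li}"
        if loop.anchor1.overlaps(loop.anchor2):
            warnings.warn(
                f"loop {loop_id}: anchors overlap; both orientations evaluated"
            )
        for prom_anchor, ccv_anchor in (
            (loop.anchor1, loop.anchor2),
            (loop.anchor2, loop.anchor1),
        ):
            hit_genes = [
                g
                for g in sorted(prom_by_gene)
                if any(prom_anchor.overlaps(p) for p in prom_by_gene[g])
            ]
            if not hit_genes:
                continue
            for cs in ccv_sets:
                ids, k = ccvs_in_feature(cs.ccvs, [ccv_anchor])
                if not k:
                    continue
                for g in hit_genes:
                    records.append(
                        LinkageRecord(
                            g,
                            cs.signal_id,
                            "loop",
                            tuple(ids),
                            loop_id=loop_id,
                            cell_line=loop.cell_line,
                        )
                    )
    # a loop whose anchors both contain the promoter and both contain CCVs
    # would emit the same record twice; keep unique rows
    return sorted(set(records), key=lambda r: (r.gene_id, r.signal_id, r.loop_id, r.cell_line))


@dataclass
class MultiSignalTarget:
    gene_id: str
    signal_ids: tuple[str, ...]
    routes: tuple[str, ...] = field(default_factory=tuple)


def multi_signal_targets(
    records: Sequence[LinkageRecord], min_signals: int = 2
) -> list[MultiSignalTarget]:
    """Genes whose pooled linkage records span >= ``min_signals`` distinct
    signals (any mix of routes). ``min_signals=1`` lists every linked gene."""
    by_gene: dict[str, list[LinkageRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    out = []
    for gene_id in sorted(by_gene):
        recs = by_gene[gene_id]
        signals = tuple(sorted({r.signal_id for r in recs}))
        if len(signals) >= min_signals:
            out.append(
                MultiSignalTarget(
                    gene_id, signals, tuple(sorted({r.route for r in recs}))
                )
            )
    return out
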