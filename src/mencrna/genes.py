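"""Gene models, derived transcript features, and annotation filtering rules.

A mencRNA (multi-exonic non-coding RNA) gene is a captured gene that, after
filtering, has at least one transcript with >= 2 exons, overlaps the capture
universe, does not overlap protein-coding exons, and reaches a maximum FPKM
of at least 0.5 across libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .intervals import (
    CaptureUniverse,
    GenomicInterval,
    intersect_intervals,
    merge_intervals,
)

__all__ = [
    "Transcript",
    "GeneModel",
    "Feature",
    "FeatureSet",
    "PromoterMode",
    "derive_features",
    "transcript_span",
    "filter_transcripts",
    "merge_annotations",
    "GENE_MIN_FPKM",
    "ISOFORM_MIN_FPKM",
]

# Expression floors: genes with max FPKM < 0.5 across all libraries and
# isoforms with max FPKM < 0.01 are removed as likely noise/DNA artifacts.
GENE_MIN_FPKM = 0.5
ISOFORM_MIN_FPKM = 0.01

PromoterMode = Literal["upstream500", "flank500"]
PROMOTER_HALF = 500


@dataclass(frozen=True)
class Transcript:
    """An ordered exon chain on one chromosome and strand."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id} mixes chromosomes or strands"
            )
        object.__setattr__(
            self, "exons", tuple(sorted(self.exons, key=lambda e: e.start))
        )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: 5'-most base of the transcript.

        On ``+`` the first exon's start; on ``-`` the last exon's end - 1
        (the 5'-most covered base). Unstranded transcripts have no TSS for
        the upstream promoter definition; callers must check.
        """
        if self.strand == "-":
            return self.end - 1
        return self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def promoter(self, mode: PromoterMode = "upstream500") -> GenomicInterval:
        """Promoter interval under either definition.

        ``upstream500``: the 500 bp strictly upstream of the TSS (strand
        required). ``flank500``: TSS base +/- 500 bp (1001 bp). Truncated at
        position 0; never extends to negative coordinates.
        """
        if mode == "upstream500":
            if self.strand == ".":
                raise ValueError(
                    f"transcript {self.transcript_id} is unstranded; "
                    "upstream500 promoters need a strand"
                )
            if self.strand == "+":
                lo, hi = self.start - PROMOTER_HALF, self.start
            else:
                lo, hi = self.end, self.end + PROMOTER_HALF
        elif mode == "flank500":
            tss = self.tss
            lo, hi = tss - PROMOTER_HALF, tss + PROMOTER_HALF + 1
        else:
            raise ValueError(f"unknown promoter mode {mode!r}")
        lo = max(lo, 0)
        if lo >= hi:  # TSS at chromosome edge, upstream flank fully clipped
            raise ValueError(
                f"promoter of {self.transcript_id} is empty after clipping at 0"
            )
        return GenomicInterval(self.chrom, lo, hi, self.strand)


@dataclass
class GeneModel:
    """A gene: one or more transcripts plus a biotype label."""

    gene_id: str
    transcripts: list[Transcript]
    biotype: str = "other"  # {mencRNA, protein_coding, other}

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def tss(self) -> int:
        """Gene-level TSS: the 5'-most transcript TSS (strand-aware)."""
        tsss = [t.tss for t in self.transcripts]
        return max(tsss) if self.strand == "-" else min(tsss)

    def exon_union(self) -> list[GenomicInterval]:
        return merge_intervals(e for t in self.transcripts for e in t.exons)

    def is_multi_exonic(self) -> bool:
        return any(t.n_exons >= 2 for t in self.transcripts)


@dataclass(frozen=True)
class Feature:
    """An interval tagged with its gene and transcript of origin."""

    interval: GenomicInterval
    gene_id: str
    transcript_id: str


@dataclass
class FeatureSet:
    """Derived exon / intron / promoter features of a gene set."""

    exons: list[Feature] = field(default_factory=list)
    introns: list[Feature] = field(default_factory=list)
    promoters: list[Feature] = field(default_factory=list)
    promoter_mode: PromoterMode = "upstream500"

    def kind(self, kind: str) -> list[Feature]:
        if kind == "exon":
            return self.exons
        if kind == "intron":
            return self.introns
        if kind == "promoter":
            return self.promoters
        raise ValueError(f"unknown feature kind {kind!r}")

    def intervals(self, kind: str) -> list[GenomicInterval]:
        return [f.interval for f in self.kind(kind)]


def derive_features(
    genes: Sequence[GeneModel],
    promoter_mode: PromoterMode = "upstream500",
    kinds: Sequence[str] = ("exon", "intron", "promoter"),
) -> FeatureSet:
    """Exons, introns and promoters for every transcript of every gene.

    Introns are exactly the gaps between consecutive exons of a transcript,
    so re-unioning a transcript's exons and introns reconstructs its span.
    Gene-level queries union the per-transcript promoters. A promoter fully
    clipped away at the chromosome start is skipped with a warning; an
    unstranded transcript under ``upstream500`` is an error.
    """
    import warnings

    fs = FeatureSet(promoter_mode=promoter_mode)
    for g in genes:
        for t in g.transcripts:
            if "exon" in kinds:
                fs.exons.extend(Feature(e, g.gene_id, t.transcript_id) for e in t.exons)
            if "intron" in kinds:
                fs.introns.extend(
                    Feature(iv, g.gene_id, t.transcript_id) for iv in t.introns()
                )
            if "promoter" in kinds:
                try:
                    prom = t.promoter(promoter_mode)
                except ValueError as exc:
                    if "unstranded" in str(exc):
                        raise
                    warnings.warn(str(exc))
                    continue
                fs.promoters.append(Feature(prom, g.gene_id, t.transcript_id))
    return fs


def transcript_span(t: Transcript) -> GenomicInterval:
    return GenomicInterval(t.chrom, t.start, t.end, t.strand)


def _same_strand_exon_overlap(
    gene: GeneModel, coding_exons_by_strand: Mapping[str, list[GenomicInterval]]
) -> bool:
    strands = ("+", "-") if gene.strand == "." else (gene.strand,)
    for s in strands:
        coding = coding_exons_by_strand.get(s, [])
        if intersect_intervals(gene.exon_union(), coding):
            return True
    return False


def _opposite_strand_exon_overlap(
    gene: GeneModel, coding_exons_by_strand: Mapping[str, list[GenomicInterval]]
) -> bool:
    if gene.strand == ".":
        return False
    opp = "-" if gene.strand == "+" else "+"
    return bool(intersect_intervals(gene.exon_union(), coding_exons_by_strand.get(opp, [])))


def _coding_exons_by_strand(coding: Iterable[GeneModel]) -> dict[str, list[GenomicInterval]]:
    by: dict[str, list[GenomicInterval]] = {"+": [], "-": []}
    for g in coding:
        for t in g.transcripts:
            for e in t.exons:
                if e.strand in by:
                    by[e.strand].append(e)
    return {s: merge_intervals(ivs) for s, ivs in by.items()}


def filter_transcripts(
    candidates: Sequence[GeneModel],
    gene_max_fpkm: Mapping[str, float],
    isoform_max_fpkm: Mapping[str, float],
    universe: CaptureUniverse,
    coding: Sequence[GeneModel] = (),
    gene_min_fpkm: float = GENE_MIN_FPKM,
    isoform_min_fpkm: float = ISOFORM_MIN_FPKM,
) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    """Apply the captured-transcript retention rules.

    A candidate gene is retained iff it is multi-exonic, overlaps the capture
    universe by >= 1 bp, has no same-strand exonic bp overlap with a
    protein-coding exon, and reaches ``max FPKM >= gene_min_fpkm`` in some
    library. Isoforms with ``max FPKM < isoform_min_fpkm`` are dropped from
    retained genes (a gene losing all isoforms is removed).

    Returns ``(retained genes, removal log)`` where the log holds
    ``(gene_id or transcript_id, reason)`` rows with reasons in
    ``{single_exon, outside_capture, coding_overlap, low_expression,
    low_isoform_expression, no_isoforms_left}``.
    """
    for g in candidates:
        if g.gene_id not in gene_max_fpkm:
            raise KeyError(f"no expression record for gene {g.gene_id}")
    coding_by_strand = _coding_exons_by_strand(coding)
    retained: list[GeneModel] = []
    log: list[tuple[str, str]] = []
    for g in candidates:
        if not g.is_multi_exonic():
            log.append((g.gene_id, "single_exon"))
            continue
        if not intersect_intervals(g.exon_union(), universe.regions):
            log.append((g.gene_id, "outside_capture"))
            continue
        if _same_strand_exon_overlap(g, coding_by_strand):
            log.append((g.gene_id, "coding_overlap"))
            continue
        if gene_max_fpkm[g.gene_id] < gene_min_fpkm:
            log.append((g.gene_id, "low_expression"))
            continue
        kept_iso = []
        for t in g.transcripts:
            iso_fpkm = isoform_max_fpkm.get(t.transcript_id)
            if iso_fpkm is not None and iso_fpkm < isoform_min_fpkm:
                log.append((t.transcript_id, "low_isoform_expression"))
            else:
                kept_iso.append(t)
        if not kept_iso:
            log.append((g.gene_id, "no_isoforms_left"))
            continue
        retained.append(GeneModel(g.gene_id, kept_iso, g.biotype))
    return retained, log


def merge_annotations(
    captured: Sequence[GeneModel],
    captured_gene_max_fpkm: Mapping[str, float],
    reference: Sequence[GeneModel],
    gene_min_fpkm: float = GENE_MIN_FPKM,
) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    """Merge captured genes with a reference annotation.

    Resolution rule for a captured/reference exonic overlap: if the captured
    gene's max FPKM is below ``gene_min_fpkm`` the captured gene is removed,
    otherwise the reference gene is excluded. Captured genes whose exons
    overlap (>= 1 bp) a protein-coding reference exon on the *opposite*
    strand are excluded regardless (unstranded downstream quantification
    cannot separate them).

    Returns ``(merged annotation, removal log)``.
    """
    ref_coding = [g for g in reference if g.biotype == "protein_coding"]
    coding_by_strand = _coding_exons_by_strand(ref_coding)

    kept_captured: list[GeneModel] = []
    log: list[tuple[str, str]] = []
    dropped_ref: set[str] = set()
    for g in captured:
        if _opposite_strand_exon_overlap(g, coding_by_strand):
            log.append((g.gene_id, "opposite_strand_coding_overlap"))
            continue
        overlapping_refs = [
            r
            for r in reference
            if intersect_intervals(g.exon_union(), r.exon_union())
        ]
        if overlapping_refs:
            fpkm = captured_gene_max_fpkm.get(g.gene_id, 0.0)
            if fpkm < gene_min_fpkm:
                log.append((g.gene_id, "low_expression_vs_reference"))
                continue
            for r in overlapping_refs:
                if r.gene_id not in dropped_ref:
                    dropped_ref.add(r.gene_id)
                    log.append((r.gene_id, "superseded_by_captured"))
        kept_captured.append(g)
    merged = kept_captured + [r for r in reference if r.gene_id not in dropped_ref]
    return merged, log
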