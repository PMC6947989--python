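"""Readers and writers for the pipeline's file formats.

BED intervals are used natively (0-based half-open). GTF is converted from
1-based inclusive coordinates on read (via pyranges) and back on write.
Variant tables carry 1-based positions in the file and are converted to
0-based in memory. All writers emit deterministically ordered text so a
rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pyranges as pr

from .capture_qc import SpikeInTable
from .ccv import CCVSet, RiskSignal, Variant
from .genes import GeneModel, Transcript
from .intervals import CaptureUniverse, GenomicInterval
from .linkage import ChromatinLoop, LinkageRecord

__all__ = [
    "read_bed",
    "write_bed",
    "read_universe",
    "read_gtf",
    "write_gtf",
    "read_variants",
    "write_ccv_bed",
    "read_bedpe",
    "write_bedpe",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_linkage_tsv",
    "read_spikein_tsv",
]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "."
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | os.PathLike,
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None or iv.strand != ".":
                name = names[i] if names is not None else "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_universe(path: str | os.PathLike) -> CaptureUniverse:
    return CaptureUniverse(read_bed(path))


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def read_gtf(path: str | os.PathLike, biotype_attr: str = "gene_biotype") -> list[GeneModel]:
    """Load gene models from GTF exon records (1-based inclusive on disk)."""
    df = pr.read_gtf(str(path)).df
    df = df[df["Feature"] == "exon"]
    genes: list[GeneModel] = []
    for gene_id, gdf in df.groupby("gene_id", sort=True):
        transcripts = []
        for tid, tdf in gdf.groupby("transcript_id", sort=True):
            exons = tuple(
                GenomicInterval(
                    str(r.Chromosome), int(r.Start), int(r.End), str(r.Strand)
                )
                for r in tdf.itertuples(index=False)
            )
            transcripts.append(Transcript(str(tid), str(gene_id), exons))
        biotype = "other"
        if biotype_attr in gdf.columns:
            vals = gdf[biotype_attr].dropna().unique()
            if len(vals):
                biotype = str(vals[0])
        genes.append(GeneModel(str(gene_id), transcripts, biotype))
    return genes


def write_gtf(
    genes: Sequence[GeneModel], path: str | os.PathLike, source: str = "mencrna"
) -> None:
    """Deterministic GTF writer (exon rows only, 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: g.gene_id):
            for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
                for e in t.exons:
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'gene_biotype "{g.biotype}";'
                    )
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand if e.strand != '.' else '.'}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# variants / CCVs
# ---------------------------------------------------------------------------


def read_variants(path: str | os.PathLike) -> list[RiskSignal]:
    """Variant TSV: signal_id, variant_id, chrom, pos (1-based), p_assoc."""
    df = pd.read_csv(path, sep="\t")
    required = {"signal_id", "variant_id", "chrom", "pos", "p_assoc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns {sorted(missing)}")
    signals = []
    for sid, sdf in df.groupby("signal_id", sort=True):
        variants = [
            Variant(str(r.variant_id), str(r.chrom), int(r.pos) - 1, float(r.p_assoc))
            for r in sdf.itertuples(index=False)
        ]
        region = (
            str(sdf["region_id"].iloc[0]) if "region_id" in sdf.columns else str(sid)
        )
        signals.append(RiskSignal(str(sid), region, variants))
    return signals


def write_variants(signals: Sequence[RiskSignal], path: str | os.PathLike) -> None:
    rows = []
    for s in sorted(signals, key=lambda s: s.signal_id):
        for v in sorted(s.variants, key=lambda v: (v.chrom, v.pos, v.variant_id)):
            rows.append(
                {
                    "signal_id": s.signal_id,
                    "region_id": s.region_id,
                    "variant_id": v.variant_id,
                    "chrom": v.chrom,
                    "pos": v.pos + 1,
                    "p_assoc": v.p_assoc,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ccv_bed(ccv_sets: Sequence[CCVSet], path: str | os.PathLike) -> None:
    """CCVs as BED6 with the signal id in the name field."""
    with open(path, "w") as fh:
        for cs in sorted(ccv_sets, key=lambda c: c.signal_id):
            for v in cs.ccvs:
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.pos + 1}\t{cs.signal_id}:{v.variant_id}"
                    f"\t0\t.\n"
                )


# ---------------------------------------------------------------------------
# BEDPE loops
# ---------------------------------------------------------------------------


def read_bedpe(path: str | os.PathLike) -> list[ChromatinLoop]:
    """BEDPE with name, score, strands, and a trailing cell_line column."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    loops = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(row[6]) if len(row) > 6 else f"loop{i}"
        score = float(row[7]) if len(row) > 7 and str(row[7]) != "." else None
        cell = str(row[10]) if len(row) > 10 else ""
        loops.append(
            ChromatinLoop(
                GenomicInterval(str(row[0]), int(row[1]), int(row[2])),
                GenomicInterval(str(row[3]), int(row[4]), int(row[5])),
                cell_line=cell,
                loop_id=name,
                score=score,
            )
        )
    return loops


def write_bedpe(loops: Sequence[ChromatinLoop], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for loop in loops:
            a, b = loop.anchor1, loop.anchor2
            score = "." if loop.score is None else f"{loop.score:g}"
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{loop.loop_id}\t{score}\t.\t.\t{loop.cell_line}\n"
            )


# ---------------------------------------------------------------------------
# matrices and tables
# ---------------------------------------------------------------------------


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Genes/variants x samples TSV with the id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t")


def write_removal_log(log: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    pd.DataFrame(log, columns=["id", "reason"]).to_csv(path, sep="\t", index=False)


def write_linkage_tsv(records: Sequence[LinkageRecord], path: str | os.PathLike) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "signal_id": r.signal_id,
            "route": r.route,
            "loop_id": r.loop_id,
            "cell_line": r.cell_line,
            "evidence_variants": ",".join(r.variant_ids),
        }
        for r in sorted(
            records, key=lambda r: (r.gene_id, r.signal_id, r.route, r.loop_id, r.cell_line)
        )
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "signal_id", "route", "loop_id", "cell_line", "evidence_variants"],
    ).to_csv(path, sep="\t", index=False)


def read_spikein_tsv(
    path: str | os.PathLike, library_id: str = "", captured: bool = True
) -> SpikeInTable:
    df = pd.read_csv(path, sep="\t")
    return SpikeInTable(df, library_id=library_id, captured=captured)


def write_spikein_tsv(t: SpikeInTable, path: str | os.PathLike) -> None:
    t.table.to_csv(path, sep="\t", index=False)


def read_expression_mapping(path: str | os.PathLike) -> Mapping[str, float]:
    """Two-column TSV (id, max_fpkm) -> dict."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def write_expression_mapping(
    mapping: Mapping[str, float], path: str | os.PathLike, id_col: str = "id"
) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=[id_col, "max_fpkm"]
    ).to_csv(path, sep="\t", index=False)
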