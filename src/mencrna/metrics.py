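"""Tissue specificity (Tau) and looped-pair co-expression comparison.

Tau summarizes how concentrated a gene's expression is across tissues:
tau = sum_i (1 - x_i / x_max) / (N - 1), 0 for uniform expression and 1 for
single-tissue expression. The looped-pair test asks whether mencRNA-mRNA
pairs whose promoters are joined by a chromatin loop are more co-expressed
than nearby non-looped pairs (TSS distance <= 1 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genes import GeneModel, derive_features
from .linkage import ChromatinLoop

__all__ = [
    "tau",
    "tau_table",
    "filter_coexpression_genes",
    "looped_pair_test",
    "PairCorrelation",
]


def tau(x: Sequence[float]) -> float:
    """Tissue-specificity index of one per-tissue expression vector.

    The vector is expected on the log2(value + 1) scale (see
    :func:`tau_table`). All-zero vectors have no defined tau (NaN).
    """
    v = np.asarray(x, dtype=float)
    if v.size < 2:
        raise ValueError("tau needs >= 2 tissues")
    if (v < 0).any():
        raise ValueError("tau input must be non-negative")
    vmax = v.max()
    if vmax == 0:
        return float("nan")
    t = float((1.0 - v / vmax).sum() / (v.size - 1))
    return min(max(t, 0.0), 1.0)


def tau_table(panel: pd.DataFrame, log_transform: bool = True) -> pd.Series:
    """Tau per gene for a genes x tissues mean-expression panel.

    Applies log2(x + 1) first unless the panel is already transformed.
    """
    x = panel.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    return pd.Series(
        [tau(row) if row.max() > 0 else np.nan for row in x],
        index=panel.index,
        name="tau",
    )


def filter_coexpression_genes(m: pd.DataFrame, min_nonzero_frac: float = 0.2,
                              min_mad: float = 1.0) -> list[str]:
    """Genes expressed in >= 20% of samples with MAD >= 1 across samples.

    MAD is the raw median absolute deviation (no consistency factor).
    """
    x = m.to_numpy(dtype=float)
    nonzero = (x > 0).mean(axis=1) >= min_nonzero_frac
    mad = np.median(np.abs(x - np.median(x, axis=1, keepdims=True)), axis=1)
    keep = nonzero & (mad >= min_mad)
    return [g for g, k in zip(m.index, keep) if k]


@dataclass(frozen=True)
class PairCorrelation:
    gene_a: str  # mencRNA
    gene_b: str  # protein-coding
    r: float
    looped: bool
    distance: int


def _promoters_by_gene(genes: Sequence[GeneModel]) -> dict[str, list]:
    fs = derive_features(genes, promoter_mode="flank500")
    by: dict[str, list] = {}
    for f in fs.promoters:
        by.setdefault(f.gene_id, []).append(f.interval)
    return by


def looped_pair_test(
    expression: pd.DataFrame,
    menc_genes: Sequence[GeneModel],
    coding_genes: Sequence[GeneModel],
    loops: Sequence[ChromatinLoop],
    window: int = 1_000_000,
    method: str = "pearson",
) -> tuple[list[PairCorrelation], float, float]:
    """Compare |r| between looped and non-looped mencRNA-mRNA pairs.

    Candidate pairs are mencRNA x protein-coding genes on the same
    chromosome with TSS-to-TSS distance <= ``window``. A pair is looped iff
    some loop (any cell line) joins their promoters (±500 bp around the
    TSS), one promoter per anchor. Correlation is computed on the supplied
    (normalized) expression; groups are compared with a two-sided
    Mann-Whitney U test on |r|.

    Returns ``(pairs, U statistic, p)``; p is NaN when a group is empty.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    menc_prom = _promoters_by_gene(menc_genes)
    cod_prom = _promoters_by_gene(coding_genes)

    pairs: list[PairCorrelation] = []
    for ga in menc_genes:
        if ga.gene_id not in expression.index:
            continue
        xa = expression.loc[ga.gene_id].to_numpy(dtype=float)
        for gb in coding_genes:
            if gb.gene_id not in expression.index or gb.chrom != ga.chrom:
                continue
            dist = abs(ga.tss - gb.tss)
            if dist > window:
                continue
            xb = expression.loc[gb.gene_id].to_numpy(dtype=float)
            if method == "pearson":
                r = float(np.corrcoef(xa, xb)[0, 1])
            else:
                r = float(sps.spearmanr(xa, xb).statistic)
            looped = _pair_is_looped(
                menc_prom.get(ga.gene_id, []), cod_prom.get(gb.gene_id, []), loops
            )
            pairs.append(PairCorrelation(ga.gene_id, gb.gene_id, r, looped, dist))

    looped_r = [abs(p.r) for p in pairs if p.looped and np.isfinite(p.r)]
    other_r = [abs(p.r) for p in pairs if not p.looped and np.isfinite(p.r)]
    if not looped_r or not other_r:
        return pairs, float("nan"), float("nan")
    stat, p = sps.mannwhitneyu(looped_r, other_r, alternative="two-sided")
    return pairs, float(stat), float(p)


def _pair_is_looped(proms_a, proms_b, loops: Sequence[ChromatinLoop]) -> bool:
    for loop in loops:
        for a1, a2 in ((loop.anchor1, loop.anchor2), (loop.anchor2, loop.anchor1)):
            if any(a1.overlaps(p) for p in proms_a) and any(
                a2.overlaps(p) for p in proms_b
            ):
                return True
    return False
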