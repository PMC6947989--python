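"""Risk signals and credible causal variant (CCV) sets.

A GWAS signal's CCV set is the variants whose association p-values lie
within two orders of magnitude of the lead (smallest-p) variant:
``p <= 100 * p_lead``, boundary inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genes import FeatureSet
from .intervals import GenomicInterval, merge_intervals

__all__ = ["Variant", "RiskSignal", "CCVSet", "CCV_FACTOR", "derive_ccvs", "ccvs_in_feature"]

logger = logging.getLogger(__name__)

CCV_FACTOR = 100.0  # "within two orders of magnitude" of the lead p-value


@dataclass(frozen=True)
class Variant:
    """A point variant (1 bp; 0-based position) with an association p-value."""

    variant_id: str
    chrom: str
    pos: int
    p_assoc: float

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position for {self.variant_id}")
        if not (0.0 < self.p_assoc <= 1.0):
            raise ValueError(
                f"p_assoc for {self.variant_id} must be in (0, 1], got {self.p_assoc}"
            )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1)


@dataclass
class RiskSignal:
    """An independent GWAS association signal within a risk region."""

    signal_id: str
    region_id: str
    variants: list[Variant]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError(f"signal {self.signal_id} has no variants")

    @property
    def lead(self) -> Variant:
        """The minimal-p variant; ties broken by variant_id (logged)."""
        best_p = min(v.p_assoc for v in self.variants)
        tied = sorted(
            (v for v in self.variants if v.p_assoc == best_p),
            key=lambda v: v.variant_id,
        )
        if len(tied) > 1:
            logger.info(
                "signal %s: %d variants tie at lead p=%g; chose %s",
                self.signal_id,
                len(tied),
                best_p,
                tied[0].variant_id,
            )
        return tied[0]


@dataclass
class CCVSet:
    """The credible causal variants of one signal."""

    signal_id: str
    ccvs: list[Variant] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.ccvs]


def derive_ccvs(signal: RiskSignal) -> CCVSet:
    """CCVs of a signal: variants with ``p <= 100 * p_lead`` (inclusive)."""
    lead = signal.lead
    threshold = CCV_FACTOR * lead.p_assoc
    ccvs = [v for v in signal.variants if v.p_assoc <= threshold]
    return CCVSet(signal.signal_id, sorted(ccvs, key=lambda v: (v.chrom, v.pos, v.variant_id)))


def _feature_intervals(features: FeatureSet | Iterable, kind: str | None) -> list[GenomicInterval]:
    if isinstance(features, FeatureSet):
        if kind is None:
            raise ValueError("feature kind required with a FeatureSet")
        return features.intervals(kind)
    return list(features)


def ccvs_in_feature(
    ccvs: Sequence[Variant],
    features: FeatureSet | Iterable[GenomicInterval],
    kind: str | None = None,
) -> tuple[list[str], int]:
    """Distinct variants whose point ``[pos, pos+1)`` overlaps a feature.

    ``features`` may be a :class:`FeatureSet` (with ``kind``) or a plain
    interval iterable. Returns ``(sorted variant ids, count)``.
    """
    ivs = merge_intervals(_feature_intervals(features, kind))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in tmp.items():
        starts = np.array([p[0] for p in pairs], dtype=np.int64)
        ends = np.array([p[1] for p in pairs], dtype=np.int64)
        by_chrom[chrom] = (starts, ends)
    hits: set[str] = set()
    for v in ccvs:
        entry = by_chrom.get(v.chrom)
        if entry is None:
            continue
        starts, ends = entry
        k = int(np.searchsorted(starts, v.pos, side="right")) - 1
        if k >= 0 and v.pos < ends[k]:
            hits.add(v.variant_id)
    return sorted(hits), len(hits)
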