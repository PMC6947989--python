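"""Feature-restricted CCV enrichment with a circular-permutation null.

Fold enrichment compares the proportion of CCVs falling in an annotation
(exons, introns or promoters of mencRNA genes) with the proportion of the
capture universe that annotation covers. Significance comes from two
routes: a base-pair hypergeometric test, and an empirical test in which
each transcript's annotations are rotated by a uniform random offset around
its circularized capture region — preserving the sizes and relative
positions of all features belonging to the same transcript — while the CCVs
stay fixed.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .ccv import Variant, ccvs_in_feature
from .genes import Feature, FeatureSet, GeneModel, PromoterMode, derive_features
from .intervals import CaptureUniverse, GenomicInterval, coverage_within

__all__ = [
    "EnrichmentResult",
    "fold_enrichment",
    "hypergeom_test",
    "permute_annotation",
    "permutation_test",
]


@dataclass
class EnrichmentResult:
    """Observed vs permutation-expected CCV overlap for one feature class."""

    feature_name: str
    observed: int
    expected_mean: float
    ci95: tuple[float, float]
    fold: float
    p_empirical: float
    p_hypergeom: float
    n_permutations: int
    seed: int
    n_ccv: int = 0
    n_ccv_dropped: int = 0

    def as_dict(self) -> dict:
        d = {
            "feature": self.feature_name,
            "observed": self.observed,
            "expected_mean": self.expected_mean,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "fold": self.fold,
            "p_empirical": self.p_empirical,
            "p_hypergeom": self.p_hypergeom,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_ccv": self.n_ccv,
            "n_ccv_dropped": self.n_ccv_dropped,
        }
        return d


def _in_universe(
    ccvs: Sequence[Variant], universe: CaptureUniverse
) -> tuple[list[Variant], int]:
    kept, seen = [], set()
    dropped = 0
    for v in ccvs:
        if v.variant_id in seen:
            continue
        seen.add(v.variant_id)
        if universe.contains_point(v.chrom, v.pos):
            kept.append(v)
        else:
            dropped += 1
    return kept, dropped


def fold_enrichment(
    ccvs: Sequence[Variant],
    feature: Iterable[GenomicInterval],
    universe: CaptureUniverse,
) -> float:
    """(fraction of CCVs in feature) / (fraction of universe covered by feature).

    CCVs outside the universe are dropped with a warning. ``fold`` is 0 when
    both overlap and coverage are 0, and ``inf`` (with a warning) when the
    feature covers no universe bp yet some CCV overlaps it.
    """
    kept, dropped = _in_universe(ccvs, universe)
    if dropped:
        warnings.warn(f"{dropped} CCVs outside the capture universe were dropped")
    if not kept:
        raise ValueError("no CCVs inside the capture universe")
    feature = list(feature)
    _, frac = coverage_within(feature, universe)
    _, k = ccvs_in_feature(kept, feature)
    if frac == 0.0:
        if k == 0:
            return 0.0
        warnings.warn("CCV overlap with a zero-coverage feature; fold is infinite")
        return math.inf
    return (k / len(kept)) / frac


def hypergeom_test(
    k_in: int, n_ccv: int, bp_feature_in_universe: int, bp_universe: int
) -> float:
    """Upper-tail hypergeometric p for >= ``k_in`` of ``n_ccv`` CCV positions
    landing in ``bp_feature_in_universe`` of ``bp_universe`` universe bp,
    drawing positions without replacement."""
    if bp_universe <= 0 or n_ccv <= 0:
        raise ValueError("degenerate hypergeometric totals")
    if k_in > n_ccv or bp_feature_in_universe > bp_universe:
        raise ValueError("hypergeometric counts exceed their totals")
    return float(stats.hypergeom.sf(k_in - 1, bp_universe, bp_feature_in_universe, n_ccv))


# ---------------------------------------------------------------------------
# circular permutation
# ---------------------------------------------------------------------------


def _transcript_offset_rng(seed: int, transcript_id: str) -> np.random.Generator:
    # counter-based Philox stream keyed on (seed, transcript id) so results
    # do not depend on transcript iteration order
    key = zlib.crc32(transcript_id.encode("utf-8"))
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([seed, key])))


def _wrap_interval(s: int, e: int, delta: int, length: int) -> list[tuple[int, int]]:
    """Shift region-relative [s, e) by delta modulo a region of given length."""
    s2 = (s + delta) % length
    e2 = s2 + (e - s)
    if e2 <= length:
        return [(s2, e2)]
    return [(s2, length), (0, e2 - length)]


def _group_features_by_transcript(
    features: Sequence[Feature],
) -> dict[str, list[Feature]]:
    by: dict[str, list[Feature]] = {}
    for f in features:
        by.setdefault(f.transcript_id, []).append(f)
    return by


def _transcript_region(
    feats: Sequence[Feature], universe: CaptureUniverse
) -> GenomicInterval:
    """The capture region a transcript's features rotate in.

    Each transcript is assigned to exactly one region — the one containing
    its 5'-most feature base; features crossing a region edge are clipped to
    the region and a transcript spanning two regions is an error.
    """
    tid = feats[0].transcript_id
    anchor = min((f.interval.start, f.interval.chrom) for f in feats)
    idx = universe.region_index_at(anchor[1], anchor[0])
    if idx is None:
        # fully outside the universe: signalled by caller dropping it
        raise KeyError(tid)
    region = universe.regions[idx]
    for f in feats:
        other = universe.region_index_at(f.interval.chrom, f.interval.start)
        if other is not None and other != idx:
            raise ValueError(f"transcript {tid} spans two capture regions")
    span = max(f.interval.end for f in feats) - min(f.interval.start for f in feats)
    if span > region.length:
        raise ValueError(f"transcript {tid} is longer than its capture region")
    return region


def permute_annotation(
    features: FeatureSet | Sequence[Feature],
    universe: CaptureUniverse,
    offsets: Mapping[str, int] | None = None,
    rng: np.random.Generator | None = None,
    kind: str = "exon",
) -> list[Feature]:
    """One structure-preserving rotation of transcript annotations.

    All features of a transcript shift by a single offset, drawn uniformly
    in ``[0, region_length)`` (or given via ``offsets``), with coordinates
    wrapping modulo the transcript's capture region; a feature crossing the
    region end splits into two wrapped pieces. Sizes and intra-transcript
    relative positions are preserved. Features are clipped to their region
    before rotation.
    """
    feats = features.kind(kind) if isinstance(features, FeatureSet) else list(features)
    by_t = _group_features_by_transcript(feats)
    if offsets is None and rng is None:
        rng = np.random.default_rng()
    out: list[Feature] = []
    for tid in sorted(by_t):
        tfeats = by_t[tid]
        region = _transcript_region(tfeats, universe)
        length = region.length
        delta = (
            int(offsets[tid]) % length
            if offsets is not None
            else int(rng.integers(0, length))
        )
        for f in tfeats:
            s = max(f.interval.start, region.start) - region.start
            e = min(f.interval.end, region.end) - region.start
            if s >= e:
                continue
            for s2, e2 in _wrap_interval(s, e, delta, length):
                out.append(
                    Feature(
                        GenomicInterval(
                            region.chrom,
                            region.start + s2,
                            region.start + e2,
                            f.interval.strand,
                        ),
                        f.gene_id,
                        f.transcript_id,
                    )
                )
    return out


def _delta_bounds(p: int, feats: list[tuple[int, int]], length: int) -> np.ndarray:
    """Sorted half-open boundaries of the offsets delta for which a CCV at
    region-relative position ``p`` is covered by the rotated features.

    A feature [s, e) shifted by delta covers p iff (p - delta) mod L in
    [s, e), i.e. delta in [p - e + 1, p - s] mod L — an offset window of the
    feature's own length. Membership is tested by searchsorted parity.
    """
    pieces: list[tuple[int, int]] = []
    for s, e in feats:
        a = (p - e + 1) % length
        b = (p - s) % length + 1  # half-open end
        if a < b:
            pieces.append((a, b))
        else:
            pieces.append((a, length))
            if b > 0:
                pieces.append((0, b))
    pieces.sort()
    # merge touching pieces so parity search stays valid
    merged: list[list[int]] = []
    for a, b in pieces:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return np.array([x for ab in merged for x in ab], dtype=np.int64)


def permutation_test(
    ccvs: Sequence[Variant],
    genes: Sequence[GeneModel],
    feature_kind: str,
    universe: CaptureUniverse,
    n: int = 100_000,
    seed: int = 0,
    promoter_mode: PromoterMode = "upstream500",
    add_one: bool = False,
) -> EnrichmentResult:
    """Empirical CCV-overlap enrichment against the circular-rotation null.

    CCVs are held fixed; every transcript's annotations are independently
    rotated within its circularized capture region in each of ``n``
    permutations, and the number of distinct overlapping CCVs is recomputed.
    ``p_empirical`` is the fraction of permutations with overlap >= observed
    (optionally with an add-one correction). The normal-approximation 95% CI
    of the permutation mean, the fold enrichment and the bp-unit
    hypergeometric p are reported alongside.
    """
    if feature_kind not in ("exon", "intron", "promoter"):
        raise ValueError(f"invalid feature kind {feature_kind!r}")
    if n < 100:
        warnings.warn(f"n={n} permutations is very small; p resolution is 1/{n}")

    fs = derive_features(genes, promoter_mode=promoter_mode, kinds=(feature_kind,))
    feats = fs.kind(feature_kind)
    kept, dropped = _in_universe(ccvs, universe)
    if not kept:
        raise ValueError("no CCVs inside the capture universe")

    by_t = _group_features_by_transcript(feats)

    # region-relative CCV positions, grouped by region index
    ccv_region: dict[int, list[int]] = {}
    for v in kept:
        idx = universe.region_index_at(v.chrom, v.pos)
        assert idx is not None
        ccv_region.setdefault(idx, []).append(
            v.pos - universe.regions[idx].start
        )

    # per-transcript clipped region-relative features + offset streams
    counts = np.zeros(n, dtype=np.int64)
    observed = 0
    for ridx, positions in sorted(ccv_region.items()):
        region = universe.regions[ridx]
        length = region.length
        pos_arr = positions
        cover = np.zeros((n, len(pos_arr)), dtype=bool)
        cover_obs = np.zeros(len(pos_arr), dtype=bool)
        for tid in sorted(by_t):
            tfeats = by_t[tid]
            try:
                t_region = _transcript_region(tfeats, universe)
            except KeyError:
                continue  # transcript entirely outside the universe
            if t_region != region:
                continue
            rel = []
            for f in tfeats:
                s = max(f.interval.start, region.start) - region.start
                e = min(f.interval.end, region.end) - region.start
                if s < e:
                    rel.append((s, e))
            if not rel:
                continue
            deltas = _transcript_offset_rng(seed, tid).integers(0, length, size=n)
            for j, p in enumerate(pos_arr):
                bounds = _delta_bounds(p, rel, length)
                if bounds.size == 0:
                    continue
                cover[:, j] |= (np.searchsorted(bounds, deltas, side="right") % 2) == 1
                cover_obs[j] |= (int(np.searchsorted(bounds, 0, side="right")) % 2) == 1
        counts += cover.sum(axis=1)
        observed += int(cover_obs.sum())

    expected_mean = float(counts.mean())
    se = float(counts.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    ci95 = (expected_mean - 1.96 * se, expected_mean + 1.96 * se)
    ge = int((counts >= observed).sum())
    p_emp = (ge + 1) / (n + 1) if add_one else ge / n

    feature_ivs = fs.intervals(feature_kind)
    bp_feat, frac = coverage_within(feature_ivs, universe)
    _, k_in = ccvs_in_feature(kept, feature_ivs)
    if frac == 0.0:
        fold = 0.0 if k_in == 0 else math.inf
    else:
        fold = (k_in / len(kept)) / frac
    p_hyp = hypergeom_test(k_in, len(kept), bp_feat, universe.total_bp)

    return EnrichmentResult(
        feature_name=feature_kind,
        observed=observed,
        expected_mean=expected_mean,
        ci95=ci95,
        fold=fold,
        p_empirical=float(p_emp),
        p_hypergeom=p_hyp,
        n_permutations=n,
        seed=seed,
        n_ccv=len(kept),
        n_ccv_dropped=dropped,
    )
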