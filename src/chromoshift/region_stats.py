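"""Region-level comparative statistics.

Catalog union (UCSC-style per-base UNION), overlap classification of one
region list against a reference catalog, per-region mean signal, paired
t-tests of wild-type vs mutant means, length-matched random control
regions, and 5-color chromatin-type composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import GenomicInterval, SignalTrack

CHROMATIN_TYPES = ("BLACK", "BLUE", "GREEN", "RED", "YELLOW")


# ---------------------------------------------------------------------------
# Interval arithmetic


def union_catalogs(catalogs: Sequence[Sequence[GenomicInterval]]) -> List[GenomicInterval]:
    """Per-base union of several region catalogs.

    Overlapping or bookended intervals merge into maximal intervals; output
    is sorted by (chrom, start). Idempotent and order-invariant.
    """
    pooled = sorted((iv for cat in catalogs for iv in cat),
                    key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: List[GenomicInterval] = []
    for iv in pooled:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def _trees(regions: Iterable[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def classify_overlap(query: Sequence[GenomicInterval],
                     reference: Sequence[GenomicInterval],
                     min_bp: int = 1) -> Tuple[List[GenomicInterval], List[GenomicInterval]]:
    """Partition query regions by overlap with a reference catalog.

    A query region is "overlapping" iff it shares at least ``min_bp`` bases
    with any single reference region (half-open: a bookended pair shares 0
    bases). The partition is exhaustive and exclusive.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _trees(reference)
    hits: List[GenomicInterval] = []
    misses: List[GenomicInterval] = []
    for q in query:
        tree = trees.get(q.chrom)
        found = False
        if tree is not None:
            for item in tree.overlap(q.start, q.end):
                shared = min(q.end, item.end) - max(q.start, item.begin)
                if shared >= min_bp:
                    found = True
                    break
        (hits if found else misses).append(q)
    return hits, misses


def _intersection_bp(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    """Total shared bases between two interval sets (each unioned first)."""
    ua, ub = union_catalogs([a]), union_catalogs([b])
    trees = _trees(ub)
    total = 0
    for iv in ua:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for item in tree.overlap(iv.start, iv.end):
            total += min(iv.end, item.end) - max(iv.start, item.begin)
    return total


# ---------------------------------------------------------------------------
# Per-region signal


@dataclass
class RegionSummary:
    """Mean signal of one region per sample, with coverage bookkeeping."""

    interval: GenomicInterval
    means: Dict[str, float]
    n_bins: int
    covered: bool


def region_means(tracks: Dict[str, Sequence[SignalTrack]],
                 regions: Sequence[GenomicInterval]) -> List[RegionSummary]:
    """Mean non-missing bin value per region and sample.

    A bin belongs to a region when its midpoint lies inside the region
    (the same midpoint rule used for fragments and peaks). Regions with no
    covered bins are flagged ``covered=False`` and carry NaN means.
    """
    sample_names = list(tracks)
    by_chrom: Dict[str, Dict[str, SignalTrack]] = {}
    for name in sample_names:
        for t in tracks[name]:
            by_chrom.setdefault(t.chrom, {})[name] = t
    out: List[RegionSummary] = []
    for region in regions:
        chrom_tracks = by_chrom.get(region.chrom, {})
        means: Dict[str, float] = {}
        n_bins = 0
        for name in sample_names:
            t = chrom_tracks.get(name)
            if t is None:
                means[name] = float("nan")
                continue
            mids = t.bin_midpoints()
            inside = (mids >= region.start) & (mids < region.end)
            vals = t.values[inside]
            vals = vals[np.isfinite(vals)]
            n_bins = max(n_bins, vals.size)
            means[name] = float(vals.mean()) if vals.size else float("nan")
        out.append(RegionSummary(region, means, n_bins, covered=n_bins > 0))
    return out


@dataclass
class PairedTResult:
    """Classical paired t-test: t, degrees of freedom, two-sided P."""

    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Paired t-test of per-region values: d = x - y, df = n - 1.

    A zero-variance difference vector makes t undefined; the result is
    flagged degenerate with NaN statistics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length vectors with n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        return PairedTResult(float("nan"), x.size - 1, float("nan"), degenerate=True)
    res = stats.ttest_rel(x, y)
    return PairedTResult(float(res.statistic), x.size - 1, float(res.pvalue))


# ---------------------------------------------------------------------------
# Random control regions


def random_regions(n: int,
                   genome_lengths: Dict[str, int],
                   length_source: Sequence[GenomicInterval],
                   seed: int = 0,
                   max_retries: int = 1000) -> List[GenomicInterval]:
    """Length-matched random control regions (default use: n = 1000).

    Lengths are resampled with replacement from ``length_source``;
    chromosomes are drawn proportionally to their length and start
    positions uniformly over valid placements. Overlaps among the random
    regions are permitted. A sampled length that fits no chromosome is
    resampled up to ``max_retries`` times, then an error is raised.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n and not length_source:
        raise ValueError("length_source is empty")
    rng = np.random.default_rng(seed)
    chroms = list(genome_lengths)
    sizes = np.array([genome_lengths[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    lengths = np.array([iv.length for iv in length_source], dtype=int)
    out: List[GenomicInterval] = []
    for i in range(n):
        for attempt in range(max_retries):
            length = int(lengths[rng.integers(len(lengths))])
            c = int(rng.choice(len(chroms), p=weights))
            limit = genome_lengths[chroms[c]] - length
            if limit >= 0:
                start = int(rng.integers(0, limit + 1))
                out.append(GenomicInterval(chroms[c], start, start + length,
                                           name=f"random_{i + 1}"))
                break
        else:
            raise ValueError("could not place a sampled length on any chromosome")
    return out


# ---------------------------------------------------------------------------
# Chromatin-type composition


def chromatin_composition(regions: Sequence[GenomicInterval],
                          annotation: Sequence[GenomicInterval]) -> Dict[str, float]:
    """Fraction of region bases covered by each of the five chromatin types.

    ``annotation`` is BED4-style with the type name in the name column.
    Regions are unioned first so shared bases count once; the returned dict
    includes an ``unannotated`` remainder so the fractions sum to 1 (types
    are assumed mutually disjoint, as in the 5-color genome partition).
    """
    region_union = union_catalogs([regions])
    total = sum(iv.length for iv in region_union)
    if total == 0:
        raise ValueError("regions cover zero bases")
    by_type: Dict[str, List[GenomicInterval]] = {t: [] for t in CHROMATIN_TYPES}
    for iv in annotation:
        if iv.name not in by_type:
            raise ValueError(f"unknown chromatin type {iv.name!r}")
        by_type[iv.name].append(iv)
    fractions = {t: _intersection_bp(region_union, ivs) / total if ivs else 0.0
                 for t, ivs in by_type.items()}
    fractions["unannotated"] = max(0.0, 1.0 - sum(fractions.values()))
    return fractions


# ---------------------------------------------------------------------------
# Convenience


def summaries_to_frame(summaries: Sequence[RegionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"chrom": s.interval.chrom, "start": s.interval.start,
               "end": s.interval.end, "name": s.interval.name,
               "n_bins": s.n_bins, "covered": s.covered}
        row.update(s.means)
        rows.append(row)
    return pd.DataFrame(rows)
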