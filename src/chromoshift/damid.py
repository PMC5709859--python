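"""DamID-seq fragment analysis.

The unit of DamID quantification is the GATC fragment — the genomic
interval between neighboring GATC sites. Reads must start with GATC to be
retained; retained reads are summed per fragment. Enrichment of a
Dam-fusion sample over the Dam-only control is scored per fragment with a
two-sided Fisher's exact test against the rest-of-library totals,
expressed in signed -log10(P) units (positive = fusion-enriched, so
profiles plot upward peaks). Peaks are fragments significant at a
Benjamini-Hochberg FDR threshold (default 5%) on the enrichment side,
with adjacent significant fragments merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomicInterval


# ---------------------------------------------------------------------------
# GATC fragmentation and read handling


def gatc_fragment(genome) -> List[GenomicInterval]:
    """Split each chromosome at the start of every GATC occurrence.

    Fragment boundaries sit at GATC start coordinates; the leading fragment
    runs from 0 to the first site, the trailing one to the chromosome end.
    N bases never match. GATC is its own reverse complement, so scanning
    the forward strand alone is exhaustive.
    """
    fragments: List[GenomicInterval] = []
    for chrom in genome:
        seq = genome[chrom]
        boundaries = [0]
        pos = seq.find("GATC")
        while pos != -1:
            if pos > boundaries[-1]:
                boundaries.append(pos)
            pos = seq.find("GATC", pos + 1)
        boundaries.append(len(seq))
        if boundaries[-1] == boundaries[-2]:
            boundaries.pop()
        for start, end in zip(boundaries[:-1], boundaries[1:]):
            fragments.append(GenomicInterval(chrom, start, end))
    return fragments


class DamRead(NamedTuple):
    """A mapped read: chromosome, 0-based start position, sequence."""

    chrom: str
    pos: int
    sequence: str


class FilterReport(NamedTuple):
    retained: int
    discarded: int

    @property
    def retention_fraction(self) -> float:
        total = self.retained + self.discarded
        return self.retained / total if total else float("nan")


def filter_reads(reads: Iterable[DamRead]) -> Tuple[List[DamRead], FilterReport]:
    """Retain exactly the reads whose first four bases are GATC."""
    kept: List[DamRead] = []
    discarded = 0
    for read in reads:
        if read.sequence[:4].upper() == "GATC":
            kept.append(read)
        else:
            discarded += 1
    return kept, FilterReport(retained=len(kept), discarded=discarded)


def count_per_fragment(read_positions: Sequence[Tuple[str, int]],
                       fragments: Sequence[GenomicInterval]) -> np.ndarray:
    """Assign each read start to the unique fragment containing it.

    Returns one count per fragment (column total = number of reads).
    Positions on chromosomes absent from the fragment list raise an error
    listing the offending records.
    """
    by_chrom: Dict[str, List[int]] = {}
    for i, frag in enumerate(fragments):
        by_chrom.setdefault(frag.chrom, []).append(i)
    starts = {c: np.array([fragments[i].start for i in idx]) for c, idx in by_chrom.items()}
    counts = np.zeros(len(fragments), dtype=np.int64)
    bad: List[Tuple[str, int]] = []
    for chrom, pos in read_positions:
        idx = by_chrom.get(chrom)
        if idx is None:
            bad.append((chrom, pos))
            continue
        j = int(np.searchsorted(starts[chrom], pos, side="right")) - 1
        if j < 0 or pos >= fragments[idx[j]].end:
            bad.append((chrom, pos))
            continue
        counts[idx[j]] += 1
    if bad:
        shown = ", ".join(f"{c}:{p}" for c, p in bad[:10])
        raise ValueError(f"{len(bad)} read position(s) outside the fragment set: {shown}")
    return counts


# ---------------------------------------------------------------------------
# Fragment table


@dataclass
class GATCFragmentTable:
    """GATC fragments tiling each chromosome plus per-sample read counts.

    Backed by a DataFrame with columns chrom, start, end and one integer
    column per sample. Fragments must be disjoint, sorted and bookended
    (each chromosome tiled without gaps).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.df.columns):
            raise ValueError("fragment table needs chrom, start, end columns")
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts[1:] != ends[:-1]).any():
                raise ValueError(f"fragments on {chrom} do not tile the chromosome")
            if (starts >= ends).any():
                raise ValueError(f"empty fragment on {chrom}")
        for name in self.sample_names:
            if (self.df[name] < 0).any():
                raise ValueError(f"negative counts in sample {name!r}")

    @property
    def sample_names(self) -> List[str]:
        return [c for c in self.df.columns if c not in ("chrom", "start", "end")]

    @property
    def fragments(self) -> List[GenomicInterval]:
        return [GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in self.df.itertuples(index=False)]

    def counts(self, sample: str) -> np.ndarray:
        return self.df[sample].to_numpy(dtype=np.int64)

    @property
    def totals(self) -> Dict[str, int]:
        return {name: int(self.df[name].sum()) for name in self.sample_names}

    @classmethod
    def from_tsv(cls, path) -> "GATCFragmentTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fisher scoring


def fisher_score(k_fus: int, k_dam: int, N_fus: int, N_dam: int) -> Tuple[float, float]:
    """Two-sided Fisher's exact test of fusion vs Dam-only counts.

    Tests the 2x2 table [[k_fus, N_fus - k_fus], [k_dam, N_dam - k_dam]].
    Returns (P, signed score) with score = -log10(P) when the sample odds
    ratio favors the fusion (enrichment), +log10(P) when it favors the
    Dam-only control (depletion), and 0 when P = 1 or the rates are equal.
    """
    if N_fus <= 0 or N_dam <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= k_fus <= N_fus and 0 <= k_dam <= N_dam):
        raise ValueError("counts must satisfy 0 <= k <= N")
    if k_fus == 0 and k_dam == 0:
        return 1.0, 0.0
    table = [[k_fus, N_fus - k_fus], [k_dam, N_dam - k_dam]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    # clamp into (0, 1]: extreme tables underflow to 0, capping the score
    p = min(max(p, 1e-300), 1.0)
    # enrichment direction from the rate comparison k_fus/N_fus vs k_dam/N_dam
    cross = k_fus * N_dam - k_dam * N_fus
    if p >= 1.0 or cross == 0:
        return p, 0.0
    sign = 1.0 if cross > 0 else -1.0
    return p, sign * (-math.log10(p))


def score_profile(table: GATCFragmentTable,
                  fusion_samples: Sequence[str],
                  dam_samples: Sequence[str]) -> pd.DataFrame:
    """Per-fragment signed Fisher profile with BH-adjusted q-values.

    Replicates are pooled (summed) per side before testing; identical
    (k_fus, k_dam) pairs share one Fisher computation since the library
    totals are fixed. Columns: chrom, start, end, k_fus, k_dam, P, q,
    score.
    """
    k_fus = sum(table.counts(s) for s in fusion_samples)
    k_dam = sum(table.counts(s) for s in dam_samples)
    N_fus = int(k_fus.sum())
    N_dam = int(k_dam.sum())
    if N_fus <= 0 or N_dam <= 0:
        raise ValueError("pooled totals must be positive")
    cache: Dict[Tuple[int, int], Tuple[float, float]] = {}
    pvals = np.empty(len(k_fus))
    scores = np.empty(len(k_fus))
    for i, (kf, kd) in enumerate(zip(k_fus, k_dam)):
        key = (int(kf), int(kd))
        if key not in cache:
            cache[key] = fisher_score(key[0], key[1], N_fus, N_dam)
        pvals[i], scores[i] = cache[key]
    q = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.empty(0)
    out = table.df[["chrom", "start", "end"]].copy()
    out["k_fus"] = k_fus
    out["k_dam"] = k_dam
    out["P"] = pvals
    out["q"] = q
    out["score"] = scores
    return out


# ---------------------------------------------------------------------------
# Peak calling and statistics


@dataclass
class PeakSet:
    """Merged significant fragments at one FDR threshold."""

    peaks: List[GenomicInterval]
    fdr: float


def call_peaks(profile: pd.DataFrame, fdr: float = 0.05,
               merge_adjacent: bool = True) -> PeakSet:
    """Fragments with q <= fdr on the enrichment side, merged when adjacent.

    ``merge_adjacent`` joins runs of bookended significant fragments into
    single peaks.
    """
    if profile.empty:
        return PeakSet(peaks=[], fdr=fdr)
    sig = profile[(profile["q"] <= fdr) & (profile["score"] > 0)]
    peaks: List[GenomicInterval] = []
    cur: Tuple[str, int, int] | None = None
    for row in sig.itertuples(index=False):
        if (merge_adjacent and cur is not None
                and row.chrom == cur[0] and row.start == cur[2]):
            cur = (cur[0], cur[1], int(row.end))
        else:
            if cur is not None:
                peaks.append(GenomicInterval(*cur))
            cur = (row.chrom, int(row.start), int(row.end))
    if cur is not None:
        peaks.append(GenomicInterval(*cur))
    return PeakSet(peaks=peaks, fdr=fdr)


def peak_density(peaks: PeakSet, regions: Sequence[GenomicInterval]) -> float:
    """Peaks per Mb of region: midpoint containment over total region length.

    A peak inside two overlapping regions counts once per region, matching
    the summed region length in the denominator.
    """
    if not regions:
        raise ValueError("no regions given")
    total_bp = sum(r.length for r in regions)
    if total_bp == 0:
        raise ValueError("zero total region length")
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    n = 0
    for peak in peaks.peaks:
        mid = peak.midpoint
        for r in by_chrom.get(peak.chrom, ()):
            if r.start <= mid < r.end:
                n += 1
    return n / (total_bp / 1e6)


def replicate_correlation(table: GATCFragmentTable, sample_a: str,
                          sample_b: str) -> float:
    """Pearson correlation of two count columns (exact formula).

    Returns NaN when either column has zero variance (undefined).
    """
    a = table.counts(sample_a).astype(float)
    b = table.counts(sample_b).astype(float)
    if len(a) < 3:
        raise ValueError("need at least 3 fragments")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
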