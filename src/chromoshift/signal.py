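"""Signal-track construction and normalization.

Covers the ChIP processing chain: reads-per-million scaling, log2
ChIP/input ratio, 1-kb sliding-window smoothing with 100-bp step, and
classic quantile normalization across samples. Missing bins (NaN) are
excluded from every computation rather than zero-filled.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .io_formats import SignalTrack


def compute_rpm(counts: SignalTrack, total_reads: float) -> SignalTrack:
    """Scale a read-count track to reads per million mapped reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    values = np.asarray(counts.values, dtype=float)
    if np.nanmin(values) < 0:
        raise ValueError("count track has negative values")
    return SignalTrack(counts.chrom, counts.bin_start, counts.step,
                       values * 1e6 / total_reads)


def log2_ratio(chip: SignalTrack, input_: SignalTrack,
               pseudocount: float = 0.0) -> SignalTrack:
    """log2((chip + pseudocount) / (input + pseudocount)) per bin.

    Bins where the denominator is zero (both samples zero at pseudocount 0,
    or input zero with chip positive) are marked missing. Default
    pseudocount is 0 for continuous tracks; use 0.5 for raw counts.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if (chip.chrom, chip.bin_start, chip.step, chip.n_bins) != (
            input_.chrom, input_.bin_start, input_.step, input_.n_bins):
        raise ValueError("chip and input tracks have mismatched bin indices")
    num = chip.values + pseudocount
    den = input_.values + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(num / den)
    out[~np.isfinite(out)] = np.nan
    return SignalTrack(chip.chrom, chip.bin_start, chip.step, out)


def smooth(track: SignalTrack, window: int = 1000, step: int = 100) -> SignalTrack:
    """Sliding-window mean: default 1-kb window advanced in 100-bp steps.

    The output bin anchored at offset ``bin_start + k*step`` is the mean of
    the non-missing input bins intersecting ``[k*step, k*step + window)``
    (relative to ``bin_start``); windows with no data are missing. Window
    and step must be multiples of the underlying bin width.
    """
    b = track.step
    if window < b:
        raise ValueError(f"window ({window}) must be >= the bin width ({b})")
    if window % b or step % b:
        raise ValueError("window and step must be multiples of the bin width")
    if window < step:
        raise ValueError("window must be >= step")
    w, s = window // b, step // b
    n = track.n_bins
    finite = np.isfinite(track.values)
    vals = np.where(finite, track.values, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0], np.cumsum(finite)))
    starts = np.arange(0, n, s)
    ends = np.minimum(starts + w, n)
    sums = csum[ends] - csum[starts]
    cnts = ccnt[ends] - ccnt[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return SignalTrack(track.chrom, track.bin_start, step, means)


# ---------------------------------------------------------------------------
# Multi-sample matrices and quantile normalization


def tracks_to_matrix(samples: Dict[str, Sequence[SignalTrack]]) -> pd.DataFrame:
    """Stack per-chromosome tracks of several samples into one matrix.

    Index is (chrom, bin start); every sample must be on the identical bin
    grid. The bin width is recorded in ``df.attrs["step"]``.
    """
    if not samples:
        raise ValueError("no samples given")
    names = list(samples)
    ref = samples[names[0]]
    grid = [(t.chrom, t.bin_start, t.step, t.n_bins) for t in ref]
    step = ref[0].step
    for name in names[1:]:
        other = [(t.chrom, t.bin_start, t.step, t.n_bins) for t in samples[name]]
        if other != grid:
            raise ValueError(f"sample {name!r} is not on the shared bin grid")
    index = pd.MultiIndex.from_arrays(
        [
            np.concatenate([[t.chrom] * t.n_bins for t in ref]),
            np.concatenate([t.bin_start + np.arange(t.n_bins) * t.step for t in ref]),
        ],
        names=["chrom", "start"],
    )
    df = pd.DataFrame(
        {name: np.concatenate([t.values for t in samples[name]]) for name in names},
        index=index,
    )
    df.attrs["step"] = step
    return df


def matrix_to_tracks(df: pd.DataFrame, step: int | None = None) -> Dict[str, List[SignalTrack]]:
    """Inverse of :func:`tracks_to_matrix`."""
    step = step if step is not None else df.attrs.get("step")
    if step is None:
        raise ValueError("bin width unknown; pass step=")
    out: Dict[str, List[SignalTrack]] = {name: [] for name in df.columns}
    for chrom, sub in df.groupby(level="chrom", sort=False):
        starts = sub.index.get_level_values("start").to_numpy()
        for name in df.columns:
            out[name].append(SignalTrack(str(chrom), int(starts[0]), int(step),
                                         sub[name].to_numpy()))
    return out


def quantile_normalize(matrix: pd.DataFrame, return_mask: bool = False):
    """Classic quantile normalization across >= 2 sample columns.

    Operates on complete rows only: each column's rank-r value is replaced
    by the mean of all columns' rank-r values, with ties sharing the mean
    of their tied ranks' reference values. Rows with any missing cell pass
    through unchanged; ``return_mask=True`` additionally returns the
    boolean complete-row mask so callers can flag them.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization requires >= 2 columns")
    values = matrix.to_numpy(dtype=float)
    complete = ~np.isnan(values).any(axis=1)
    out = values.copy()
    sub = values[complete]
    if sub.shape[0] > 0:
        reference = np.sort(sub, axis=0).mean(axis=1)
        normed = np.empty_like(sub)
        for j in range(sub.shape[1]):
            col = sub[:, j]
            order = np.argsort(col, kind="mergesort")
            sorted_vals = col[order]
            change = np.concatenate(([True], sorted_vals[1:] != sorted_vals[:-1]))
            run_id = np.cumsum(change) - 1
            sums = np.bincount(run_id, weights=reference)
            cnts = np.bincount(run_id)
            normed[order, j] = (sums / cnts)[run_id]
        out[complete] = normed
    result = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    result.attrs.update(matrix.attrs)
    if return_mask:
        return result, complete
    return result


def average_tracks(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Bin-wise mean of replicate tracks on one shared grid (NaN-aware)."""
    first = tracks[0]
    for t in tracks[1:]:
        if (t.chrom, t.bin_start, t.step, t.n_bins) != (
                first.chrom, first.bin_start, first.step, first.n_bins):
            raise ValueError("replicate tracks are not on the same bin grid")
    stacked = np.vstack([t.values for t in tracks])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    return SignalTrack(first.chrom, first.bin_start, first.step, mean)


def normalize_genotype_tracks(
    tracks: Dict[str, List[List[SignalTrack]]],
    scope: str = "genotype",
) -> Dict[str, List[SignalTrack]]:
    """Quantile-normalize replicate tracks and average them per genotype.

    ``scope="genotype"`` (default) normalizes replicates within each
    genotype, preserving genuine between-genotype signal differences;
    ``scope="all"`` normalizes every sample against a common reference
    distribution, which assumes the genotypes share one signal
    distribution. Returns one averaged track list per genotype.
    """
    if scope not in ("genotype", "all"):
        raise ValueError("scope must be 'genotype' or 'all'")
    flat: Dict[str, Sequence[SignalTrack]] = {}
    for genotype, reps in tracks.items():
        for rep, chrom_tracks in enumerate(reps, start=1):
            flat[f"{genotype}_rep{rep}"] = chrom_tracks

    def _qn(names: List[str]) -> Dict[str, List[SignalTrack]]:
        if len(names) < 2:
            return {name: list(flat[name]) for name in names}
        df = quantile_normalize(tracks_to_matrix({n: flat[n] for n in names}))
        return matrix_to_tracks(df)

    normalized: Dict[str, List[SignalTrack]] = {}
    if scope == "all":
        normalized = _qn(list(flat))
    else:
        for genotype, reps in tracks.items():
            names = [f"{genotype}_rep{r + 1}" for r in range(len(reps))]
            normalized.update(_qn(names))

    averaged: Dict[str, List[SignalTrack]] = {}
    for genotype, reps in tracks.items():
        names = [f"{genotype}_rep{r + 1}" for r in range(len(reps))]
        n_chrom = len(flat[names[0]])
        averaged[genotype] = [
            average_tracks([normalized[name][c] for name in names])
            for c in range(n_chrom)
        ]
    return averaged
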