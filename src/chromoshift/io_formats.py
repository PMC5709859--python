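"""Genomic file formats and core coordinate types.

All coordinates in this package are 0-based half-open (BED-native):
an interval [start, end) covers bases start .. end-1. Every consumer of
:class:`GenomicInterval` relies on this single convention; the constructor
is the shared validator.

Supported formats: BED3/BED4/BED5 for regions and peaks, bedGraph
(uniform-width bins) for signal tracks, FASTA for genome sequence, and a
two-column UCSC ``chrom.sizes`` dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from Bio import SeqIO


class ParseError(ValueError):
    """Malformed input file; the message names the file and line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open span [start, end).

    Parameters
    ----------
    chrom : str
        Chromosome name; must be nonempty.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    name : str, optional
        Free-form identifier (BED column 4).
    score : float, optional
        Numeric annotation (BED column 5).
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (isinstance(self.start, (int, np.integer)) and isinstance(self.end, (int, np.integer))):
            raise ValueError("start/end must be integers")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SignalTrack:
    """A fixed-step binned numeric track on one chromosome.

    Bin ``i`` covers ``[bin_start + i*step, bin_start + (i+1)*step)``.
    Missing bins carry NaN and are excluded from normalization and from
    HMM emission likelihoods (never zero-filled: zero is a meaningful
    log-ratio).
    """

    chrom: str
    bin_start: int
    step: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a nonempty 1-D sequence")

    @property
    def n_bins(self) -> int:
        return self.values.size

    def bin_midpoints(self) -> np.ndarray:
        return self.bin_start + np.arange(self.n_bins) * self.step + self.step / 2.0

    def copy(self) -> "SignalTrack":
        return SignalTrack(self.chrom, self.bin_start, self.step, self.values.copy())


@dataclass
class Genome:
    """Ordered map of chromosome name -> upper-case DNA sequence."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} has zero length")

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> List[GenomicInterval]:
    """Read BED3+ into intervals, preserving file order and 0-based
    half-open coordinates unchanged."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: non-numeric score") from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(float(iv.score)))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path) -> List[SignalTrack]:
    """Read a uniform-bin bedGraph into one SignalTrack per chromosome.

    Within a chromosome, spans must be sorted, non-overlapping and all of
    one width; gaps (multiples of that width) become NaN bins. Ragged bin
    widths raise :class:`ParseError` instructing to re-bin.
    """
    spans: Dict[str, List[tuple]] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad coordinates or value") from exc
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end")
            if chrom not in spans:
                spans[chrom] = []
                order.append(chrom)
            spans[chrom].append((start, end, value, lineno))

    tracks: List[SignalTrack] = []
    for chrom in order:
        rows = spans[chrom]
        step = rows[0][1] - rows[0][0]
        bin_start = rows[0][0]
        values: List[float] = []
        prev_end = bin_start
        for start, end, value, lineno in rows:
            if end - start != step:
                raise ParseError(
                    f"{path}: line {lineno}: bin width {end - start} != {step}; "
                    "re-bin the track to uniform-width spans"
                )
            if start < prev_end:
                raise ParseError(f"{path}: line {lineno}: overlapping or unsorted spans")
            gap = start - prev_end
            if gap % step != 0:
                raise ParseError(
                    f"{path}: line {lineno}: gap of {gap} bp is not a multiple of the "
                    f"{step}-bp bin width; re-bin the track"
                )
            values.extend([math.nan] * (gap // step))
            values.append(value)
            prev_end = end
        tracks.append(SignalTrack(chrom, bin_start, step, np.array(values)))
    return tracks


def write_bedgraph(tracks: Sequence[SignalTrack], path) -> None:
    """Write tracks as bedGraph; NaN bins are emitted as gaps.

    Values are written with ``repr`` so a read-back reproduces them exactly.
    """
    with open(path, "w") as fh:
        for track in tracks:
            starts = track.bin_start + np.arange(track.n_bins) * track.step
            for start, value in zip(starts, track.values):
                if math.isnan(value):
                    continue
                fh.write(f"{track.chrom}\t{start}\t{start + track.step}\t{float(value)!r}\n")


# ---------------------------------------------------------------------------
# FASTA and chrom.sizes


def read_fasta(path) -> Genome:
    """Read FASTA; sequences are upper-cased, duplicate headers rejected."""
    sequences: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ParseError(f"{path}: duplicate FASTA header {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return Genome(sequences)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    """Read the two-column UCSC chrom.sizes dialect (name<TAB>length)."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer length") from exc
    return sizes


def write_chrom_sizes(sizes: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")
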