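"""Synthetic genomes with planted SuUR-sensitive chromatin structure.

The generator plants two classes of H3K27me3 domains on a multi-chromosome
genome and emits everything the analysis pipeline consumes:

* SSRs (SuUR-sensitive regions): moderate wild-type log2(ChIP/input) signal
  (mean 0.41) that collapses in the SuUR mutant (mean -0.06), Polycomb-free.
* SNRs (SuUR-non-sensitive regions): high signal in both genotypes,
  Polycomb-bound.
* Background near 0 everywhere else.

Per-bin probe noise is i.i.d. Gaussian. DamID material consists of GATC
fragments (exponential inter-site spacing) with Poisson read counts;
Dam-fusion enrichment over Dam-only is confined to discrete binding sites
inside bound domains (Pc in SNRs only; SUUR in both SSRs and SNRs, stronger
in SNRs). All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import (
    GenomicInterval,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
)


class DomainLabel(str, enum.Enum):
    """Label of a genomic base: planted domain class or background."""

    SSR = "SSR"
    SNR = "SNR"
    BACKGROUND = "BACKGROUND"

    __str__ = str.__str__  # stringify as the bare value, numpy-comparison safe


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Signal means are log2(ChIP/input) units on the already-normalized scale;
    ``mu_ssr_wt``/``mu_ssr_mut`` default to the wild-type/mutant SSR class
    means (0.41 / -0.06) and ``ssr_length_mean`` to the 214-kb average SSR
    length. ``mu_snr`` is a free parameter (SNRs carry "high" signal; 1.5 is
    a plausible strong-domain value). DamID ``depth`` is the mean read count
    per GATC fragment; fold-enrichments apply at discrete binding sites
    covering a ``site_frac`` fraction of fragments inside bound domains.
    """

    n_chroms: int = 2
    chrom_length: int = 10_000_000
    bin_step: int = 100
    n_ssr: int = 20
    n_snr: int = 15
    ssr_length_mean: float = 214_000.0
    snr_length_mean: float = 120_000.0
    length_sigma: float = 0.4          # log-normal shape of domain lengths
    min_domain_length: int = 30_000    # callable under the >30-kb span rule
    mu_ssr_wt: float = 0.41
    mu_ssr_mut: float = -0.06
    mu_snr: float = 1.5
    mu_bg: float = 0.0
    sigma_noise: float = 0.3
    n_replicates: int = 2
    gatc_mean_spacing: float = 256.0
    depth: float = 20.0
    enrich_snr_pc: float = 8.0
    enrich_snr_suur: float = 6.0
    enrich_ssr_suur: float = 2.5
    site_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        positives = dict(
            n_chroms=self.n_chroms,
            chrom_length=self.chrom_length,
            bin_step=self.bin_step,
            ssr_length_mean=self.ssr_length_mean,
            snr_length_mean=self.snr_length_mean,
            min_domain_length=self.min_domain_length,
            sigma_noise=self.sigma_noise,
            n_replicates=self.n_replicates,
        )
        for key, value in positives.items():
            if value <= 0:
                raise ValueError(f"{key} must be positive, got {value}")
        if self.n_ssr < 0 or self.n_snr < 0:
            raise ValueError("domain counts must be non-negative")
        if self.gatc_mean_spacing < 8:
            raise ValueError("gatc_mean_spacing must be >= 8 bp")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        for key in ("enrich_snr_pc", "enrich_snr_suur", "enrich_ssr_suur"):
            if getattr(self, key) < 1:
                raise ValueError(f"{key} must be >= 1")
        if self.enrich_snr_suur < self.enrich_ssr_suur:
            raise ValueError("SUUR enrichment in SNRs must be >= that in SSRs")
        if not (0 < self.site_frac <= 1):
            raise ValueError("site_frac must be in (0, 1]")
        expected = (self.n_ssr * self.ssr_length_mean + self.n_snr * self.snr_length_mean)
        if expected >= 0.8 * self.n_chroms * self.chrom_length:
            raise ValueError("expected total domain length exceeds 80% of the genome; "
                             "use fewer or shorter domains")

    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {name: self.chrom_length for name in self.chrom_names}


@dataclass
class SyntheticTruth:
    """Planted domains (sorted, non-overlapping) plus the generating config."""

    domains: List[Tuple[GenomicInterval, DomainLabel]]
    config: SimulationConfig
    seed: int

    def domains_of(self, label: DomainLabel) -> List[GenomicInterval]:
        return [iv for iv, lab in self.domains if lab is label]

    def label_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Label an array of base positions on one chromosome.

        Returns an object array of :class:`DomainLabel`.
        """
        labels = np.empty(len(positions), dtype=object)
        labels[:] = DomainLabel.BACKGROUND
        for iv, lab in self.domains:
            if iv.chrom != chrom:
                continue
            inside = (positions >= iv.start) & (positions < iv.end)
            labels[inside] = lab
        return labels

    def bin_labels(self, chrom: str, n_bins: int, bin_start: int = 0,
                   step: int | None = None) -> np.ndarray:
        """Per-bin labels, by bin midpoint."""
        step = step if step is not None else self.config.bin_step
        mids = bin_start + np.arange(n_bins) * step + step // 2
        return self.label_positions(chrom, mids)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, reproducible substream named by purpose."""
    digest = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "little"))


def plant_domains(config: SimulationConfig) -> SyntheticTruth:
    """Place non-overlapping SSR/SNR domains on the synthetic genome.

    Lengths are log-normal around the configured class means (clipped below
    at ``min_domain_length`` so every planted domain is callable under the
    >30-kb span rule) and snapped to the bin grid. Domains are assigned to
    chromosomes proportionally to free space and separated by at least one
    bin of background.
    """
    rng = _rng(config.seed, "domains")
    step = config.bin_step

    def _lengths(n: int, mean: float) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        sigma = config.length_sigma
        mu = np.log(mean) - sigma**2 / 2.0  # log-normal with the stated mean
        raw = rng.lognormal(mu, sigma, size=n)
        raw = np.maximum(raw, config.min_domain_length + step)
        return np.round(raw / step).astype(int) * step

    entries = [(int(l), DomainLabel.SSR) for l in _lengths(config.n_ssr, config.ssr_length_mean)]
    entries += [(int(l), DomainLabel.SNR) for l in _lengths(config.n_snr, config.snr_length_mean)]
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]

    # Greedy assignment to chromosomes, probability proportional to free space.
    free = {name: config.chrom_length for name in config.chrom_names}
    assigned: Dict[str, List[Tuple[int, DomainLabel]]] = {name: [] for name in config.chrom_names}
    for length, label in entries:
        # room needed: the domain plus one separating bin per domain already there
        candidates = [c for c in config.chrom_names
                      if free[c] >= length + step * (len(assigned[c]) + 2)]
        if not candidates:
            raise ValueError(
                "cannot pack the requested domains into the genome; "
                "reduce n_ssr/n_snr or the length means"
            )
        weights = np.array([free[c] for c in candidates], dtype=float)
        chrom = candidates[rng.choice(len(candidates), p=weights / weights.sum())]
        assigned[chrom].append((length, label))
        free[chrom] -= length

    domains: List[Tuple[GenomicInterval, DomainLabel]] = []
    for chrom in config.chrom_names:
        items = assigned[chrom]
        if not items:
            continue
        total = sum(length for length, _ in items)
        n_gaps = len(items) + 1
        spare_bins = (config.chrom_length - total) // step - n_gaps
        # one guaranteed background bin per gap, spare distributed at random
        extra = rng.multinomial(spare_bins, np.full(n_gaps, 1.0 / n_gaps)) if spare_bins > 0 \
            else np.zeros(n_gaps, dtype=int)
        pos = 0
        for (length, label), add in zip(items, extra[:-1]):
            pos += (1 + int(add)) * step
            domains.append((GenomicInterval(chrom, pos, pos + length, name=label.value), label))
            pos += length
    domains.sort(key=lambda item: (item[0].chrom, item[0].start))
    return SyntheticTruth(domains=domains, config=config, seed=config.seed)


def _class_mean(label: DomainLabel, genotype: str, config: SimulationConfig) -> float:
    if label is DomainLabel.SSR:
        return config.mu_ssr_wt if genotype == "wt" else config.mu_ssr_mut
    if label is DomainLabel.SNR:
        return config.mu_snr
    return config.mu_bg


def simulate_chip_tracks(truth: SyntheticTruth) -> Dict[str, List[List[SignalTrack]]]:
    """Per-genotype, per-replicate binned log2(ChIP/input) tracks.

    Returns ``{"wt": [rep][chrom_track], "mut": [...]}`` where each bin is
    its label's class mean for that genotype plus Gaussian(0, sigma_noise);
    replicates are independent draws.
    """
    config = truth.config
    n_bins = config.chrom_length // config.bin_step
    out: Dict[str, List[List[SignalTrack]]] = {}
    for genotype in ("wt", "mut"):
        reps: List[List[SignalTrack]] = []
        for rep in range(config.n_replicates):
            rng = _rng(config.seed, f"chip:{genotype}:rep{rep}")
            tracks: List[SignalTrack] = []
            for chrom in config.chrom_names:
                labels = truth.bin_labels(chrom, n_bins)
                means = np.full(n_bins, config.mu_bg)
                for label in (DomainLabel.SSR, DomainLabel.SNR):
                    means[labels == label] = _class_mean(label, genotype, config)
                values = means + rng.normal(0.0, config.sigma_noise, size=n_bins)
                tracks.append(SignalTrack(chrom, 0, config.bin_step, values))
            reps.append(tracks)
        out[genotype] = reps
    return out


def simulate_gatc_fragments(chrom_lengths: Dict[str, int],
                            config: SimulationConfig) -> List[GenomicInterval]:
    """GATC fragments from exponential inter-site spacing.

    Fragments tile each chromosome exactly (disjoint, covering); the mean
    fragment length converges to ``gatc_mean_spacing``.
    """
    rng = _rng(config.seed, "gatc")
    fragments: List[GenomicInterval] = []
    for chrom, length in chrom_lengths.items():
        boundaries = [0]
        pos = 0.0
        while True:
            pos += rng.exponential(config.gatc_mean_spacing)
            site = int(np.ceil(pos))
            if site >= length:
                break
            if site > boundaries[-1]:
                boundaries.append(site)
        boundaries.append(length)
        for start, end in zip(boundaries[:-1], boundaries[1:]):
            fragments.append(GenomicInterval(chrom, start, end))
    return fragments


FACTORS = ("pc", "suur")


def _bound_mask(truth: SyntheticTruth, fragments: Sequence[GenomicInterval],
                factor: str) -> Tuple[np.ndarray, np.ndarray]:
    """(bound?, fold) per fragment for one factor, by fragment midpoint.

    Binding is punctate: inside a bound domain each fragment carries a site
    with probability ``site_frac`` (seeded), mirroring discrete peaks within
    broad domains.
    """
    config = truth.config
    n = len(fragments)
    fold = np.ones(n)
    rng = _rng(config.seed, f"sites:{factor}")
    in_domain = rng.random(n) < config.site_frac  # consumed in fragment order
    labels = np.empty(n, dtype=object)
    by_chrom: Dict[str, List[int]] = {}
    for i, frag in enumerate(fragments):
        by_chrom.setdefault(frag.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        mids = np.array([fragments[i].midpoint for i in idx])
        labs = truth.label_positions(chrom, mids)
        for j, i in enumerate(idx):
            labels[i] = labs[j]
    if factor == "pc":
        fold[(labels == DomainLabel.SNR) & in_domain] = config.enrich_snr_pc
    elif factor == "suur":
        fold[(labels == DomainLabel.SNR) & in_domain] = config.enrich_snr_suur
        fold[(labels == DomainLabel.SSR) & in_domain] = config.enrich_ssr_suur
    else:  # pragma: no cover
        raise ValueError(f"unknown factor {factor!r}")
    return fold > 1, fold


def simulate_damid_counts(truth: SyntheticTruth,
                          fragments: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Poisson read counts per GATC fragment for every DamID sample.

    Dam-only rate for a fragment is ``depth * length / gatc_mean_spacing``;
    fusion samples multiply the rate by the factor's fold-enrichment at its
    binding sites (Pc: SNRs only; SUUR: SSRs and SNRs). Columns:
    chrom, start, end, then ``{factor}_rep{r}`` and ``dam_rep{r}``.
    """
    config = truth.config
    lengths = np.array([f.length for f in fragments], dtype=float)
    base_rate = config.depth * lengths / config.gatc_mean_spacing
    table = pd.DataFrame(
        {
            "chrom": [f.chrom for f in fragments],
            "start": [f.start for f in fragments],
            "end": [f.end for f in fragments],
        }
    )
    for factor in FACTORS:
        _, fold = _bound_mask(truth, fragments, factor)
        for rep in range(config.n_replicates):
            rng = _rng(config.seed, f"counts:{factor}:rep{rep}")
            table[f"{factor}_rep{rep + 1}"] = rng.poisson(base_rate * fold)
    for rep in range(config.n_replicates):
        rng = _rng(config.seed, f"counts:dam:rep{rep}")
        table[f"dam_rep{rep + 1}"] = rng.poisson(base_rate)
    return table


CHROMATIN_TYPES = ("BLACK", "BLUE", "GREEN", "RED", "YELLOW")


def make_chromatin_annotation(truth: SyntheticTruth) -> List[GenomicInterval]:
    """Synthetic 5-color chromatin annotation matching the planted truth.

    SSRs are painted BLACK (Pc-free repressive chromatin), SNRs BLUE
    (PRC-bound), background YELLOW (active). Returned as BED4-style
    intervals with the type in the name column.
    """
    annotation: List[GenomicInterval] = []
    for chrom in truth.config.chrom_names:
        pos = 0
        length = truth.config.chrom_length
        for iv, lab in truth.domains:
            if iv.chrom != chrom:
                continue
            if iv.start > pos:
                annotation.append(GenomicInterval(chrom, pos, iv.start, name="YELLOW"))
            color = "BLACK" if lab is DomainLabel.SSR else "BLUE"
            annotation.append(GenomicInterval(chrom, iv.start, iv.end, name=color))
            pos = iv.end
        if pos < length:
            annotation.append(GenomicInterval(chrom, pos, length, name="YELLOW"))
    return annotation


def write_fixture(truth: SyntheticTruth,
                  tracks: Dict[str, List[List[SignalTrack]]],
                  fragments: Sequence[GenomicInterval],
                  counts: pd.DataFrame,
                  directory) -> Dict[str, str]:
    """Write the full fixture (BED truth, bedGraph tracks, TSV counts,
    chrom.sizes, manifest) to ``directory``; returns {role: path}.

    Re-running with the same config and seed reproduces byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config = truth.config
    paths: Dict[str, str] = {}

    truth_bed = directory / "truth_domains.bed"
    write_bed([iv for iv, _ in truth.domains], truth_bed)
    paths["truth_domains"] = str(truth_bed)

    sizes_path = directory / "chrom.sizes"
    write_chrom_sizes(config.chrom_lengths, sizes_path)
    paths["chrom_sizes"] = str(sizes_path)

    for genotype, reps in tracks.items():
        for rep, chrom_tracks in enumerate(reps, start=1):
            p = directory / f"{genotype}_rep{rep}.bedgraph"
            write_bedgraph(chrom_tracks, p)
            paths[f"track_{genotype}_rep{rep}"] = str(p)

    frag_path = directory / "damid_counts.tsv"
    counts.to_csv(frag_path, sep="\t", index=False)
    paths["damid_counts"] = str(frag_path)

    annotation = make_chromatin_annotation(truth)
    ann_path = directory / "chromatin_types.bed"
    write_bed(annotation, ann_path)
    paths["chromatin_types"] = str(ann_path)

    manifest = directory / "manifest.txt"
    with open(manifest, "w") as fh:
        for key, value in sorted(asdict(config).items()):
            fh.write(f"config.{key}: {value}\n")
        fh.write(f"seed: {truth.seed}\n")
        for role in sorted(paths):
            fh.write(f"file.{role}: {Path(paths[role]).name}\n")
    paths["manifest"] = str(manifest)
    return paths


def simulate_all(config: SimulationConfig):
    """Convenience: truth, ChIP tracks, GATC fragments and DamID counts."""
    truth = plant_domains(config)
    tracks = simulate_chip_tracks(truth)
    fragments = simulate_gatc_fragments(config.chrom_lengths, config)
    counts = simulate_damid_counts(truth, fragments)
    return truth, tracks, fragments, counts
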