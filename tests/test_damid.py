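import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from chromoshift.damid import (
    DamRead,
    GATCFragmentTable,
    PeakSet,
    call_peaks,
    count_per_fragment,
    filter_reads,
    fisher_score,
    gatc_fragment,
    peak_density,
    replicate_correlation,
    score_profile,
)
from chromoshift.io_formats import Genome, GenomicInterval


def hypergeom_two_sided(k_fus, k_dam, N_fus, N_dam):
    """Exhaustive two-sided Fisher P: sum of the probabilities of every
    table (same margins) no more likely than the observed one."""
    n_success = k_fus + k_dam
    kmin = max(0, n_success - N_dam)
    kmax = min(n_success, N_fus)
    support = np.arange(kmin, kmax + 1)
    probs = hypergeom.pmf(support, N_fus + N_dam, n_success, N_fus)
    observed = hypergeom.pmf(k_fus, N_fus + N_dam, n_success, N_fus)
    return float(probs[probs <= observed * (1 + 1e-12)].sum())


class TestGatcFragment:
    def test_hand_scanned_sequence(self):
        genome = Genome({"c1": "AAGATCAAAAGATCAA"})
        frags = gatc_fragment(genome)
        assert [(f.start, f.end) for f in frags] == [(0, 2), (2, 10), (10, 16)]

    def test_no_site_single_fragment(self):
        frags = gatc_fragment(Genome({"c1": "AAAACCCCGGGG"}))
        assert [(f.start, f.end) for f in frags] == [(0, 12)]

    def test_n_bases_never_match(self):
        frags = gatc_fragment(Genome({"c1": "AAGANCAAAA"}))
        assert len(frags) == 1

    def test_lengths_sum_to_chromosome(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        frags = gatc_fragment(Genome({"c1": seq}))
        assert sum(f.length for f in frags) == 5000
        assert all(a.end == b.start for a, b in zip(frags, frags[1:]))

    def test_site_at_origin_no_empty_fragment(self):
        frags = gatc_fragment(Genome({"c1": "GATCAAAA"}))
        assert [(f.start, f.end) for f in frags] == [(0, 8)]


class TestFilterReads:
    def test_rule_application(self):
        reads = [DamRead("c1", 0, "GATCAAA"), DamRead("c1", 5, "AGATCAA"),
                 DamRead("c1", 9, "gatcTT"), DamRead("c1", 2, "")]
        kept, report = filter_reads(reads)
        assert [r.pos for r in kept] == [0, 9]
        assert report == (2, 2)

    def test_all_prefixed_retention_one(self):
        kept, report = filter_reads([DamRead("c", i, "GATCA") for i in range(5)])
        assert report.retention_fraction == 1.0


class TestCountPerFragment:
    FRAGS = [GenomicInterval("c1", 0, 10), GenomicInterval("c1", 10, 30),
             GenomicInterval("c2", 0, 15)]

    def test_single_read_at_midpoint(self):
        counts = count_per_fragment([("c1", 15)], self.FRAGS)
        assert counts.tolist() == [0, 1, 0]

    def test_conservation(self, rng):
        positions = [("c1", int(p)) for p in rng.integers(0, 30, size=1000)]
        assert count_per_fragment(positions, self.FRAGS).sum() == 1000

    def test_matches_linear_scan_oracle(self, rng):
        positions = [(rng.choice(["c1", "c2"]), int(rng.integers(0, 15)))
                     for _ in range(200)]
        counts = count_per_fragment(positions, self.FRAGS)
        oracle = np.zeros(len(self.FRAGS), dtype=int)
        for chrom, pos in positions:
            for i, f in enumerate(self.FRAGS):
                if f.chrom == chrom and f.start <= pos < f.end:
                    oracle[i] += 1
        np.testing.assert_array_equal(counts, oracle)

    def test_unknown_chromosome_listed(self):
        with pytest.raises(ValueError, match="cX:5"):
            count_per_fragment([("cX", 5)], self.FRAGS)


class TestFisherScore:
    def test_equal_rates_score_zero(self):
        p, score = fisher_score(5, 5, 100, 100)
        assert p == 1.0 and score == 0.0

    def test_zero_margin_table(self):
        assert fisher_score(0, 0, 10, 10) == (1.0, 0.0)

    def test_swap_negates_score(self):
        p1, s1 = fisher_score(20, 5, 100, 100)
        p2, s2 = fisher_score(5, 20, 100, 100)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert s1 == pytest.approx(-s2, abs=1e-12)
        assert s1 > 0  # fusion-enriched side is positive

    def test_score_is_signed_log10_p(self):
        p, score = fisher_score(20, 5, 100, 100)
        assert score == pytest.approx(-math.log10(p))

    @pytest.mark.parametrize("k_fus,k_dam,N_fus,N_dam", [
        (3, 9, 12, 14), (0, 7, 10, 20), (12, 1, 25, 30), (5, 5, 10, 10),
        (1, 0, 2, 28), (15, 15, 30, 30),
    ])
    def test_matches_hypergeometric_enumeration(self, k_fus, k_dam, N_fus, N_dam):
        p, _ = fisher_score(k_fus, k_dam, N_fus, N_dam)
        assert p == pytest.approx(hypergeom_two_sided(k_fus, k_dam, N_fus, N_dam),
                                  abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fisher_score(5, 1, 0, 10)
        with pytest.raises(ValueError):
            fisher_score(11, 1, 10, 10)


def make_table(counts_by_sample, frag_len=10, chrom="c1"):
    n = len(next(iter(counts_by_sample.values())))
    df = pd.DataFrame({
        "chrom": [chrom] * n,
        "start": np.arange(n) * frag_len,
        "end": (np.arange(n) + 1) * frag_len,
    })
    for name, counts in counts_by_sample.items():
        df[name] = counts
    return GATCFragmentTable(df)


class TestScoreProfileAndPeaks:
    def test_bh_q_monotone_and_dominates_p(self, rng):
        fus = rng.poisson(20, size=300)
        fus[:20] = rng.poisson(120, size=20)
        dam = rng.poisson(20, size=300)
        table = make_table({"fus": fus, "dam": dam})
        prof = score_profile(table, ["fus"], ["dam"])
        assert (prof["q"] >= prof["P"] - 1e-15).all()
        srt = prof.sort_values("P")
        assert (np.diff(srt["q"].to_numpy()) >= -1e-12).all()

    def test_replicates_pooled(self):
        table = make_table({"f1": [5, 0], "f2": [3, 1], "d1": [2, 2]})
        prof = score_profile(table, ["f1", "f2"], ["d1"])
        assert prof["k_fus"].tolist() == [8, 1]

    def test_single_significant_fragment_is_single_peak(self):
        prof = pd.DataFrame({
            "chrom": ["c1"] * 3, "start": [0, 10, 20], "end": [10, 20, 30],
            "q": [1.0, 0.01, 1.0], "score": [0.0, 5.0, 0.0]})
        peaks = call_peaks(prof, fdr=0.05)
        assert [(p.start, p.end) for p in peaks.peaks] == [(10, 20)]

    def test_all_significant_merge_per_chromosome(self):
        prof = pd.DataFrame({
            "chrom": ["c1", "c1", "c2"], "start": [0, 10, 0], "end": [10, 20, 30],
            "q": [0.01] * 3, "score": [3.0] * 3})
        peaks = call_peaks(prof, fdr=0.05)
        assert [(p.chrom, p.start, p.end) for p in peaks.peaks] == \
            [("c1", 0, 20), ("c2", 0, 30)]

    def test_depleted_fragments_never_called(self):
        prof = pd.DataFrame({
            "chrom": ["c1"], "start": [0], "end": [10],
            "q": [0.001], "score": [-8.0]})
        assert call_peaks(prof).peaks == []

    def test_empty_profile(self):
        prof = pd.DataFrame(columns=["chrom", "start", "end", "q", "score"])
        assert call_peaks(prof).peaks == []

    def test_no_merge_flag(self):
        prof = pd.DataFrame({
            "chrom": ["c1", "c1"], "start": [0, 10], "end": [10, 20],
            "q": [0.01, 0.01], "score": [3.0, 3.0]})
        peaks = call_peaks(prof, merge_adjacent=False)
        assert len(peaks.peaks) == 2


class TestPeakDensity:
    def test_forced_arithmetic(self):
        peaks = PeakSet([GenomicInterval("c1", i * 100, i * 100 + 10)
                         for i in range(10)], 0.05)
        regions = [GenomicInterval("c1", 0, 2_000_000)]
        assert peak_density(peaks, regions) == pytest.approx(5.0)

    def test_no_peaks(self):
        assert peak_density(PeakSet([], 0.05),
                            [GenomicInterval("c1", 0, 1000)]) == 0.0

    def test_matches_midpoint_containment_oracle(self, rng):
        peaks = PeakSet([GenomicInterval("c1", int(s), int(s) + 50)
                         for s in rng.integers(0, 99_000, size=40)], 0.05)
        regions = [GenomicInterval("c1", int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, 90_000, size=8),
                                   rng.integers(1000, 10_000, size=8))]
        n = sum(1 for p in peaks.peaks for r in regions
                if r.start <= (p.start + p.end) // 2 < r.end)
        total_mb = sum(r.length for r in regions) / 1e6
        assert peak_density(peaks, regions) == pytest.approx(n / total_mb)

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError):
            peak_density(PeakSet([], 0.05), [])


class TestReplicateCorrelation:
    def test_self_correlation(self):
        table = make_table({"a": [1, 5, 9, 2], "b": [1, 5, 9, 2]})
        assert replicate_correlation(table, "a", "b") == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        table = make_table({"a": [1, 2, 3], "b": [3, 2, 1]})
        assert replicate_correlation(table, "a", "b") == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        table = make_table({"a": [2, 2, 2], "b": [1, 5, 9]})
        assert math.isnan(replicate_correlation(table, "a", "b"))

    def test_synthetic_replicates_exceed_0_9(self, small_fixture):
        """Shared fragment-length and binding-site structure dominates
        Poisson noise at default depth, as in real DamID replicates."""
        counts = small_fixture[3]
        table = GATCFragmentTable(counts)
        for sample in ("pc", "suur", "dam"):
            r = replicate_correlation(table, f"{sample}_rep1", f"{sample}_rep2")
            assert r > 0.9


class TestFragmentTableValidation:
    def test_gap_rejected(self):
        df = pd.DataFrame({"chrom": ["c1", "c1"], "start": [0, 20],
                           "end": [10, 30], "s": [1, 2]})
        with pytest.raises(ValueError, match="tile"):
            GATCFragmentTable(df)

    def test_totals(self):
        table = make_table({"a": [1, 2, 3]})
        assert table.totals == {"a": 6}

    def test_tsv_round_trip(self, tmp_path):
        table = make_table({"a": [1, 2, 3], "b": [0, 0, 7]})
        p = tmp_path / "frags.tsv"
        table.to_tsv(p)
        back = GATCFragmentTable.from_tsv(p)
        pd.testing.assert_frame_equal(table.df, back.df)
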