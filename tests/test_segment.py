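import itertools

import numpy as np
import pytest

from chromoshift.io_formats import SignalTrack
from chromoshift.segment import (
    GaussianHMM,
    Segmentation,
    build_observations,
    call_regions,
    label_states,
    segment_tracks,
)
from chromoshift.simulate import DomainLabel


def random_model(rng, n_states, dim=2):
    pi = rng.dirichlet(np.ones(n_states))
    A = rng.dirichlet(np.ones(n_states), size=n_states)
    means = rng.normal(scale=2.0, size=(n_states, dim))
    covars = []
    for _ in range(n_states):
        L = rng.normal(size=(dim, dim)) * 0.5
        covars.append(L @ L.T + 0.3 * np.eye(dim))
    model = GaussianHMM(n_states=n_states)
    model.set_parameters(pi, A, means, np.array(covars))
    return model


def brute_force_viterbi(model, X):
    """Exhaustive K^n path enumeration; ties broken toward the
    lexicographically smallest path (lower state indices first)."""
    log_b = model._log_emission(X)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.startprob_)
        log_A = np.log(model.transmat_)
    best_path, best_score = None, -np.inf
    for path in itertools.product(range(model.n_states), repeat=len(X)):
        score = log_pi[path[0]] + log_b[0, path[0]]
        for t in range(1, len(X)):
            score += log_A[path[t - 1], path[t]] + log_b[t, path[t]]
        if score > best_score + 1e-12:
            best_path, best_score = path, score
    return np.array(best_path)


class TestViterbi:
    def test_single_bin_at_state_mean(self):
        model = GaussianHMM(n_states=3).set_parameters(
            np.full(3, 1 / 3), np.full((3, 3), 1 / 3),
            np.array([[0.0, 0.0], [5.0, 5.0], [-5.0, 5.0]]),
            np.array([np.eye(2)] * 3))
        assert model.viterbi(np.array([[5.0, 5.0]]))[0] == 1

    @pytest.mark.parametrize("trial", range(20))
    def test_equals_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        K = int(rng.integers(2, 4))
        n = int(rng.integers(2, 11))
        model = random_model(rng, K)
        X = rng.normal(scale=2.0, size=(n, 2))
        np.testing.assert_array_equal(model.viterbi(X), brute_force_viterbi(model, X))

    def test_tie_broken_toward_lower_state_index(self):
        # two identical states: every path is tied, the all-zeros path wins
        model = GaussianHMM(n_states=2).set_parameters(
            np.array([0.5, 0.5]), np.full((2, 2), 0.5),
            np.zeros((2, 2)), np.array([np.eye(2)] * 2))
        path = model.viterbi(np.zeros((6, 2)))
        np.testing.assert_array_equal(path, 0)

    def test_all_missing_decodes_to_background_with_warning(self):
        model = random_model(np.random.default_rng(0), 3)
        with pytest.warns(UserWarning, match="background"):
            path = model.viterbi(np.full((5, 2), np.nan))
        np.testing.assert_array_equal(path, 0)


class TestFit:
    def test_k1_closed_form(self, rng):
        X = rng.normal(size=(400, 2)) @ np.array([[1.0, 0.3], [0.0, 0.8]])
        model = GaussianHMM(n_states=1, max_iter=5).fit([X])
        np.testing.assert_allclose(model.means_[0], X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(model.covars_[0], np.cov(X.T, bias=True), atol=1e-6)

    def test_loglik_monotone_nondecreasing(self, rng):
        X = np.concatenate([rng.normal(0, 1, size=(150, 2)),
                            rng.normal(2, 1, size=(150, 2))])
        model = GaussianHMM(n_states=2, max_iter=30, tol=1e-8, seed=1).fit([X])
        ll = np.array(model.loglik_history_)
        assert np.all(np.diff(ll) >= -1e-6)

    def test_parameter_recovery_from_known_model(self):
        """Data drawn from a known 3-state chain: EM recovers the emission
        means within 0.05 (states matched by nearest mean)."""
        rng = np.random.default_rng(42)
        true_means = np.array([[0.0, 0.0], [0.41, -0.06], [1.5, 1.5]])
        A = np.full((3, 3), 0.005)
        np.fill_diagonal(A, 0.99)
        states = [0]
        for _ in range(30_000 - 1):
            states.append(rng.choice(3, p=A[states[-1]]))
        states = np.array(states)
        X = true_means[states] + rng.normal(0, 0.3, size=(len(states), 2))
        model = GaussianHMM(n_states=3, max_iter=60, tol=1e-4, seed=0).fit([X])
        # match fitted states to truth by nearest mean
        for mu in true_means:
            d = np.linalg.norm(model.means_ - mu, axis=1)
            assert d.min() < 0.05

    def test_missing_bins_marginalized(self, rng):
        X = np.concatenate([rng.normal(0, 1, size=(200, 2)),
                            rng.normal(3, 1, size=(200, 2))])
        X_missing = X.copy()
        X_missing[::10] = np.nan
        model = GaussianHMM(n_states=2, max_iter=20, seed=0).fit([X_missing])
        assert np.isfinite(model.means_).all()
        assert np.isfinite(model.score(X_missing))

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            GaussianHMM(n_states=3).fit([rng.normal(size=(10, 2))])


class TestAgainstHmmlearn:
    """Independent cross-check: with identical fixed parameters on complete
    data, the likelihood and Viterbi path agree with hmmlearn."""

    def test_score_and_viterbi_match(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(7)
        mine = random_model(rng, 3)
        X = rng.normal(scale=2.0, size=(500, 2))
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="full",
                                   init_params="")
        ref.startprob_ = mine.startprob_
        ref.transmat_ = mine.transmat_
        ref.means_ = mine.means_
        ref.covars_ = mine.covars_
        assert mine.score(X) == pytest.approx(ref.score(X), abs=1e-6)
        np.testing.assert_array_equal(mine.viterbi(X), ref.predict(X))


class TestLabelStates:
    def _model(self, means):
        K = len(means)
        return GaussianHMM(n_states=K).set_parameters(
            np.full(K, 1.0 / K), np.full((K, K), 1.0 / K),
            np.asarray(means, float), np.array([np.eye(2)] * K))

    def test_canonical_means(self):
        labels = label_states(self._model([[0.41, -0.06], [1.5, 1.5], [0.0, 0.0]]))
        assert labels == {0: DomainLabel.SSR, 1: DomainLabel.SNR,
                          2: DomainLabel.BACKGROUND}

    def test_permutation_invariance(self):
        means = [[0.41, -0.06], [1.5, 1.5], [0.0, 0.0]]
        base = label_states(self._model(means))
        for perm in itertools.permutations(range(3)):
            permuted = label_states(self._model([means[i] for i in perm]))
            assert [permuted[j] for j in range(3)] == [base[perm[j]] for j in range(3)]

    def test_degenerate_means_warn_no_ssr(self):
        with pytest.warns(UserWarning, match="no SSR"):
            labels = label_states(self._model([[0.0, 0.0]] * 3))
        assert DomainLabel.SSR not in labels.values()

    def test_snr_requires_clearance_over_background(self):
        # second state is elevated but within delta of background: stays background
        labels = label_states(self._model([[0.5, 0.0], [0.15, 0.15], [0.0, 0.0]]),
                              delta=0.2)
        assert labels[1] is DomainLabel.BACKGROUND


class TestCallRegions:
    LABELS = {0: DomainLabel.BACKGROUND, 1: DomainLabel.SSR, 2: DomainLabel.SNR}

    def test_span_rule(self):
        # 25-kb run discarded, 40-kb run kept (100-bp bins)
        path = np.zeros(1000, dtype=int)
        path[100:350] = 1   # 25 kb
        path[500:900] = 1   # 40 kb
        seg = call_regions({"c": path}, self.LABELS, 100, min_span=30_000)
        assert [(r.interval.start, r.interval.end) for r in seg.regions] == [(50_000, 90_000)]

    def test_alternating_bins_never_survive(self):
        path = np.tile([0, 1], 2000)
        seg = call_regions({"c": path}, self.LABELS, 100, min_span=30_000, max_gap=0)
        assert seg.regions == []

    @pytest.mark.parametrize("max_gap", [0, 2])
    def test_matches_run_length_oracle(self, rng, max_gap):
        path = rng.choice([0, 1], size=500, p=[0.3, 0.7])
        min_span = 1000
        seg = call_regions({"c": path}, self.LABELS, 100,
                           min_span=min_span, max_gap=max_gap)
        # brute-force oracle: scan runs, bridge gaps <= max_gap
        runs = []
        i = 0
        while i < len(path):
            if path[i] == 1:
                j = i
                end = i
                while j < len(path):
                    if path[j] == 1:
                        end = j
                        j += 1
                    else:
                        gap = 0
                        k = j
                        while k < len(path) and path[k] == 0:
                            gap += 1
                            k += 1
                        if gap <= max_gap and k < len(path):
                            j = k
                        else:
                            break
                runs.append((i * 100, (end + 1) * 100))
                i = end + 1
            else:
                i += 1
        expected = [(a, b) for a, b in runs if b - a > min_span]
        assert [(r.interval.start, r.interval.end) for r in seg.regions] == expected

    def test_region_means_attached(self):
        path = np.array([0] * 5 + [1] * 10 + [0] * 5)
        obs = np.column_stack([np.arange(20.0), -np.arange(20.0)])
        seg = call_regions({"c": path}, self.LABELS, 100, observations={"c": obs},
                           min_span=500)
        (region,) = seg.regions
        assert region.mean_wt == pytest.approx(np.arange(5, 15).mean())
        assert region.mean_mut == pytest.approx(-np.arange(5, 15).mean())


class TestEndToEndSegmentation:
    def test_recovers_planted_domains_small(self, small_fixture):
        from chromoshift.signal import normalize_genotype_tracks

        truth, tracks, _, _ = small_fixture
        averaged = normalize_genotype_tracks(tracks)
        model, seg = segment_tracks(averaged["wt"], averaged["mut"], seed=1)
        called = {lab: seg.regions_of(lab) for lab in (DomainLabel.SSR, DomainLabel.SNR)}
        planted = {lab: truth.domains_of(lab) for lab in (DomainLabel.SSR, DomainLabel.SNR)}
        assert len(called[DomainLabel.SSR]) == len(planted[DomainLabel.SSR])
        assert len(called[DomainLabel.SNR]) == len(planted[DomainLabel.SNR])
        # every call matches a planted domain within 5 kb per boundary
        for lab in called:
            for c in called[lab]:
                match = min(planted[lab],
                            key=lambda p: abs(p.start - c.start) + abs(p.end - c.end))
                assert c.chrom == match.chrom
                assert abs(c.start - match.start) <= 5000
                assert abs(c.end - match.end) <= 5000


def test_build_observations_pairs_and_propagates_missing():
    wt = SignalTrack("c", 0, 100, np.array([1.0, np.nan, 3.0]))
    mut = SignalTrack("c", 0, 100, np.array([0.5, 1.0, np.nan]))
    obs = build_observations([wt], [mut])["c"]
    assert np.isnan(obs[1]).all() and np.isnan(obs[2]).all()
    np.testing.assert_array_equal(obs[0], [1.0, 0.5])
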