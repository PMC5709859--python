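"""Gaussian-emission HMM segmentation of paired-genotype H3K27me3 profiles.

Each genomic bin contributes a bivariate observation (wild-type value,
mutant value) of quantile-normalized log2(ChIP/input) signal. A K-state
first-order HMM with full-covariance Gaussian emissions is fitted by
Baum-Welch over all chromosomes jointly; Viterbi decoding yields a per-bin
state path. States are then mapped to domain labels by their emission
means — the SuUR-sensitive state (SSR) is the one whose wild-type mean
exceeds its mutant mean, the non-sensitive state (SNR) carries high signal
in both genotypes — and maximal same-label runs longer than 30 kb become
called regions.

The strong self-transition prior (0.99 self-loop at initialization)
encodes domain persistence; the explicit >30-kb span filter replaces an
explicit duration distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._hmm_core import forward_backward, viterbi_path
from .io_formats import GenomicInterval, SignalTrack
from .simulate import DomainLabel

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


def _check_model_arrays(startprob, transmat, means, covars) -> None:
    K = len(startprob)
    if not np.isclose(startprob.sum(), 1.0):
        raise ValueError("startprob must sum to 1")
    if transmat.shape != (K, K) or not np.allclose(transmat.sum(axis=1), 1.0):
        raise ValueError("each row of the transition matrix must sum to 1")
    if means.shape[0] != K or covars.shape[0] != K:
        raise ValueError("means/covars must have one entry per state")
    for k in range(K):
        cov = covars[k]
        if not np.allclose(cov, cov.T):
            raise ValueError(f"state {k} covariance is not symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError(f"state {k} covariance is not positive-definite")


class GaussianHMM:
    """K-state HMM with multivariate Gaussian emissions and missing data.

    Observations are (T, D) arrays; rows containing NaN are treated as
    missing and their emission term marginalizes to 1 (log 0.0), so they
    inform the path only through the transition structure.

    Parameters
    ----------
    n_states : int
        Number of hidden states (default 3: SSR, SNR, background).
    max_iter, tol : int, float
        Baum-Welch stops when the absolute log-likelihood gain drops below
        ``tol`` or after ``max_iter`` iterations.
    self_loop : float
        Initial self-transition probability; off-diagonal mass is uniform.
    cov_floor : float
        Diagonal floor added to a state covariance when it degenerates
        (state starvation); a warning is logged.
    seed : int
        Seeds the k-means initialization.

    Attributes (after :meth:`fit`)
    ------------------------------
    startprob_, transmat_, means_, covars_ : model parameters
    loglik_history_ : per-iteration total log-likelihood (non-decreasing)
    converged_ : whether the tolerance was reached before ``max_iter``
    """

    def __init__(self, n_states: int = 3, max_iter: int = 50, tol: float = 1e-2,
                 self_loop: float = 0.99, cov_floor: float = 1e-4, seed: int = 0):
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        self.n_states = n_states
        self.max_iter = max_iter
        self.tol = tol
        self.self_loop = self_loop
        self.cov_floor = cov_floor
        self.seed = seed

    # -- parameters -----------------------------------------------------

    def set_parameters(self, startprob, transmat, means, covars) -> "GaussianHMM":
        """Install explicit parameters (validated) without fitting."""
        startprob = np.asarray(startprob, dtype=float)
        transmat = np.asarray(transmat, dtype=float)
        means = np.asarray(means, dtype=float)
        covars = np.asarray(covars, dtype=float)
        _check_model_arrays(startprob, transmat, means, covars)
        self.startprob_ = startprob
        self.transmat_ = transmat
        self.means_ = means
        self.covars_ = covars
        return self

    # -- emissions ------------------------------------------------------

    def _log_emission(self, X: np.ndarray) -> np.ndarray:
        """(T, K) log N(x_t | mu_k, Sigma_k); missing rows contribute 0."""
        X = np.asarray(X, dtype=float)
        T, D = X.shape
        K = self.n_states
        missing = np.isnan(X).any(axis=1)
        log_b = np.zeros((T, K))
        obs = X[~missing]
        if obs.shape[0]:
            for k in range(K):
                cov = self.covars_[k]
                chol = np.linalg.cholesky(cov)
                diff = obs - self.means_[k]
                sol = np.linalg.solve(chol, diff.T)
                maha = np.sum(sol**2, axis=0)
                logdet = 2.0 * np.sum(np.log(np.diag(chol)))
                log_b[~missing, k] = -0.5 * (D * _LOG2PI + logdet + maha)
        return log_b

    # -- fitting --------------------------------------------------------

    def _initialize(self, stacked_obs: np.ndarray) -> None:
        K, D = self.n_states, stacked_obs.shape[1]
        rng = np.random.default_rng(self.seed)
        if K == 1:
            centers = stacked_obs.mean(axis=0, keepdims=True)
        else:
            # seeded k-means (Lloyd) on the observation vectors
            centers = stacked_obs[rng.choice(len(stacked_obs), size=K, replace=False)]
            for _ in range(25):
                d2 = ((stacked_obs[:, None, :] - centers[None]) ** 2).sum(axis=2)
                assign = d2.argmin(axis=1)
                new = np.empty_like(centers)
                for k in range(K):
                    members = stacked_obs[assign == k]
                    new[k] = members.mean(axis=0) if len(members) else centers[k]
                if np.allclose(new, centers):
                    break
                centers = new
            # deterministic state order: sort by mean vector
            centers = centers[np.lexsort(centers.T[::-1])]
        self.means_ = centers
        global_cov = np.cov(stacked_obs.T).reshape(D, D)
        self.covars_ = np.array([global_cov + self.cov_floor * np.eye(D)
                                 for _ in range(K)])
        self.startprob_ = np.full(K, 1.0 / K)
        if K == 1:
            self.transmat_ = np.ones((1, 1))
        else:
            off = (1.0 - self.self_loop) / (K - 1)
            self.transmat_ = np.full((K, K), off)
            np.fill_diagonal(self.transmat_, self.self_loop)

    def fit(self, sequences: Sequence[np.ndarray]) -> "GaussianHMM":
        """Baum-Welch EM over independent sequences (one per chromosome)."""
        sequences = [np.asarray(s, dtype=float) for s in sequences]
        if not sequences:
            raise ValueError("no observation sequences")
        D = sequences[0].shape[1]
        stacked = np.vstack(sequences)
        obs_mask = ~np.isnan(stacked).any(axis=1)
        if obs_mask.sum() < 10 * self.n_states:
            raise ValueError("need at least 10 non-missing bins per state")
        self._initialize(stacked[obs_mask])

        K = self.n_states
        prev_ll = -np.inf
        self.loglik_history_: List[float] = []
        self.converged_ = False
        for iteration in range(self.max_iter):
            total_ll = 0.0
            gamma0 = np.zeros(K)
            xi_sum = np.zeros((K, K))
            w_sum = np.zeros(K)
            wx_sum = np.zeros((K, D))
            wxx_sum = np.zeros((K, D, D))
            for X in sequences:
                log_b = self._log_emission(X)
                ll, gamma, xi, g0 = forward_backward(self.startprob_,
                                                     self.transmat_, log_b)
                if not np.isfinite(ll):
                    raise FloatingPointError("non-finite HMM log-likelihood")
                total_ll += ll
                gamma0 += g0
                xi_sum += xi
                present = ~np.isnan(X).any(axis=1)
                g = gamma[present]
                x = X[present]
                w_sum += g.sum(axis=0)
                wx_sum += g.T @ x
                for k in range(K):
                    wxx_sum[k] += (x * g[:, k:k + 1]).T @ x
            self.loglik_history_.append(total_ll)

            # M-step
            self.startprob_ = gamma0 / gamma0.sum()
            if K > 1:
                rows = xi_sum.sum(axis=1, keepdims=True)
                self.transmat_ = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-300),
                                          self.transmat_)
            for k in range(K):
                if w_sum[k] < 1e-6:
                    logger.warning("state %d starved; keeping previous parameters", k)
                    continue
                mu = wx_sum[k] / w_sum[k]
                cov = wxx_sum[k] / w_sum[k] - np.outer(mu, mu)
                cov = (cov + cov.T) / 2.0
                if np.linalg.eigvalsh(cov).min() < 1e-6:
                    logger.warning("state %d covariance degenerate; flooring", k)
                    cov = cov + self.cov_floor * np.eye(D)
                self.means_[k] = mu
                self.covars_[k] = cov

            if total_ll - prev_ll < self.tol and iteration > 0:
                self.converged_ = True
                break
            prev_ll = total_ll
        return self

    # -- inference ------------------------------------------------------

    def score(self, X: np.ndarray) -> float:
        """Log-likelihood of one observation sequence."""
        ll, *_ = forward_backward(self.startprob_, self.transmat_,
                                  self._log_emission(np.asarray(X, dtype=float)))
        return float(ll)

    def viterbi(self, X: np.ndarray) -> np.ndarray:
        """Maximum a posteriori state path (ties -> lower state index).

        An all-missing sequence decodes to state 0 with a warning.
        """
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any(axis=1).all():
            warnings.warn("all bins missing; returning the designated "
                          "background state (index 0)")
            return np.zeros(len(X), dtype=np.int64)
        with np.errstate(divide="ignore"):
            log_pi = np.log(self.startprob_)
            log_A = np.log(self.transmat_)
        return viterbi_path(log_pi, log_A, self._log_emission(X))


# ---------------------------------------------------------------------------
# State labeling and region calling


def label_states(model: GaussianHMM, delta: float = 0.2) -> Dict[int, DomainLabel]:
    """Map HMM states to domain labels from their emission means.

    SSR: the state maximizing (wt mean - mut mean), provided the contrast
    is at least ``delta``. SNR: among the remaining states, the one whose
    weaker-genotype mean is largest, provided both its means exceed the
    background level by ``delta``. Everything else is background. The
    mapping depends only on the means, so it is invariant under state
    permutation.
    """
    wt = model.means_[:, 0]
    mut = model.means_[:, 1]
    K = len(wt)
    labels = {k: DomainLabel.BACKGROUND for k in range(K)}
    contrast = wt - mut
    ssr = int(np.argmax(contrast))
    if contrast[ssr] >= delta:
        labels[ssr] = DomainLabel.SSR
    else:
        warnings.warn("no state shows the SuUR-sensitive contrast "
                      f"(max wt-mut = {contrast[ssr]:.3f} < delta={delta}); "
                      "no SSR state assigned")
        ssr = -1
    remaining = [k for k in range(K) if k != ssr]
    if remaining:
        lows = np.minimum(wt, mut)
        snr = remaining[int(np.argmax(lows[remaining]))]
        bg_states = [k for k in remaining if k != snr]
        bg_level = (np.mean([(wt[k] + mut[k]) / 2.0 for k in bg_states])
                    if bg_states else 0.0)
        if lows[snr] >= bg_level + delta:
            labels[snr] = DomainLabel.SNR
    return labels


@dataclass
class RegionCall:
    """One called region with its label and mean signal per genotype."""

    interval: GenomicInterval
    label: DomainLabel
    mean_wt: float
    mean_mut: float


@dataclass
class Segmentation:
    """Per-chromosome state paths plus span-filtered region calls."""

    state_paths: Dict[str, np.ndarray]
    state_labels: Dict[int, DomainLabel]
    regions: List[RegionCall] = field(default_factory=list)

    def regions_of(self, label: DomainLabel) -> List[GenomicInterval]:
        return [r.interval for r in self.regions if r.label is label]


def _runs(mask: np.ndarray, max_gap: int) -> List[Tuple[int, int]]:
    """Maximal true-runs of a boolean array, bridging gaps of <= max_gap."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs: List[Tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= max_gap:
            prev = i
        else:
            runs.append((int(start), int(prev) + 1))
            start = prev = i
    runs.append((int(start), int(prev) + 1))
    return runs


def call_regions(paths: Dict[str, np.ndarray],
                 state_labels: Dict[int, DomainLabel],
                 bin_step: int,
                 bin_starts: Optional[Dict[str, int]] = None,
                 observations: Optional[Dict[str, np.ndarray]] = None,
                 min_span: int = 30_000,
                 max_gap: int = 0) -> Segmentation:
    """Convert per-bin state paths into labeled regions.

    Maximal runs of one label (optionally bridging up to ``max_gap``
    dissenting bins) become intervals; intervals with length <= ``min_span``
    are discarded, implementing the "spanning over 30 kb" rule. Mean
    wild-type/mutant signal over the run's non-missing bins is attached
    when observations are supplied.
    """
    bin_starts = bin_starts or {}
    seg = Segmentation(state_paths=paths, state_labels=state_labels)
    for chrom, path in paths.items():
        offset = bin_starts.get(chrom, 0)
        lab_arr = np.array([state_labels[int(s)].value for s in path])
        obs = observations.get(chrom) if observations else None
        for label in (DomainLabel.SSR, DomainLabel.SNR):
            for lo, hi in _runs(lab_arr == label.value, max_gap):
                start = offset + lo * bin_step
                end = offset + hi * bin_step
                if end - start <= min_span:
                    continue
                mean_wt = mean_mut = float("nan")
                if obs is not None:
                    window = obs[lo:hi]
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        mean_wt = float(np.nanmean(window[:, 0]))
                        mean_mut = float(np.nanmean(window[:, 1]))
                seg.regions.append(RegionCall(
                    GenomicInterval(chrom, start, end, name=label.value),
                    label, mean_wt, mean_mut))
    seg.regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return seg


# ---------------------------------------------------------------------------
# High-level entry point


def build_observations(wt_tracks: Sequence[SignalTrack],
                       mut_tracks: Sequence[SignalTrack]) -> Dict[str, np.ndarray]:
    """Pair per-chromosome genotype tracks into (T, 2) observation arrays.

    A bin missing in either genotype is missing in both (NaN row).
    """
    obs: Dict[str, np.ndarray] = {}
    mut_by_chrom = {t.chrom: t for t in mut_tracks}
    for wt in wt_tracks:
        mut = mut_by_chrom.get(wt.chrom)
        if mut is None:
            raise ValueError(f"no mutant track for chromosome {wt.chrom}")
        if (wt.bin_start, wt.step, wt.n_bins) != (mut.bin_start, mut.step, mut.n_bins):
            raise ValueError(f"genotype tracks disagree on the bin grid for {wt.chrom}")
        X = np.column_stack([wt.values, mut.values])
        X[np.isnan(X).any(axis=1)] = np.nan
        obs[wt.chrom] = X
    return obs


def segment_tracks(wt_tracks: Sequence[SignalTrack],
                   mut_tracks: Sequence[SignalTrack],
                   n_states: int = 3,
                   min_span: int = 30_000,
                   max_gap: int = 0,
                   delta: float = 0.2,
                   seed: int = 0,
                   max_iter: int = 50,
                   tol: float = 1e-2) -> Tuple[GaussianHMM, Segmentation]:
    """Fit the HMM on paired genotype tracks and call SSR/SNR regions."""
    obs = build_observations(wt_tracks, mut_tracks)
    chroms = list(obs)
    model = GaussianHMM(n_states=n_states, max_iter=max_iter, tol=tol, seed=seed)
    model.fit([obs[c] for c in chroms])
    labels = label_states(model, delta=delta)
    paths = {c: model.viterbi(obs[c]) for c in chroms}
    bin_starts = {t.chrom: t.bin_start for t in wt_tracks}
    step = wt_tracks[0].step
    seg = call_regions(paths, labels, step, bin_starts=bin_starts,
                       observations=obs, min_span=min_span, max_gap=max_gap)
    return model, seg
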