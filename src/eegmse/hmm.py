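"""Gaussian hidden Markov models with Bakis (left-right) topology.

One model lambda = (pi, A, B) is trained per emotional class.  The
transition matrix A is constrained to its upper triangle: a state can
loop on itself, advance to the next state, or skip ahead, but never
move backwards.  Emissions are diagonal-covariance Gaussians (one
component per state).  Training uses the Baum-Welch (EM) algorithm on
multiple observation sequences: forward-backward posteriors gamma_t(i)
and xi_t(i, j) are accumulated across all sequences before each
M-step, so the updates

    pi_i  <- mean over sequences of gamma_1(i)
    a_ij  <- sum_t xi_t(i, j) / sum_t gamma_t(i)        (masked to j >= i)
    mu_j, sigma^2_j <- gamma-weighted sample moments

are the exact multi-sequence EM re-estimates and the total
log-likelihood is non-decreasing at every iteration.  Classification
scores a held-out sequence under the "high" and "low" models with the
forward recursion and takes the larger log-likelihood.  All recursions
run in the log domain: with high-dimensional diagonal Gaussians the
per-frame emission densities span thousands of nats, which underflows
the classical linear-domain scaled recursion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "GaussianHMMParams",
    "forward_loglik",
    "BakisGaussianHMM",
    "HMMEmotionClassifier",
    "classify",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianHMMParams:
    """Parameter set lambda = (pi, A, B) of one Gaussian HMM.

    ``startprob`` is pi (length Q), ``transmat`` is A (Q x Q, upper
    triangular support), ``means`` and ``variances`` are the per-state
    diagonal Gaussian emission parameters (Q x D).
    """

    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    n_mix: int = 1

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        q = self.startprob.size
        if self.transmat.shape != (q, q):
            raise ValueError("transition matrix shape does not match pi")
        if not np.allclose(self.startprob.sum(), 1.0):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("each row of A must sum to 1")
        if np.any(np.tril(self.transmat, k=-1) != 0.0):
            raise ValueError("Bakis topology violated: nonzero below diagonal")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def n_states(self) -> int:
        return self.startprob.size

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def _emission_loglik(params: GaussianHMMParams, seq: np.ndarray) -> np.ndarray:
    """log N(o_t | mu_q, diag(sigma^2_q)) for every frame/state, (T, Q)."""
    mu, var = params.means, params.variances  # (Q, D)
    const = -0.5 * (np.log(var).sum(axis=1) + var.shape[1] * _LOG2PI)  # (Q,)
    # (T, Q) quadratic form for diagonal covariance
    quad = (
        (seq ** 2) @ (1.0 / var).T
        - 2.0 * seq @ (mu / var).T
        + ((mu ** 2) / var).sum(axis=1)
    )
    return const - 0.5 * quad


def forward_loglik(params: GaussianHMMParams, seq: np.ndarray) -> float:
    """log P(O | lambda) of one observation sequence (log-domain forward)."""
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    if seq.shape[0] < 1 or seq.size == 0:
        raise ValueError("observation sequence is empty")
    if seq.shape[1] != params.n_features:
        raise ValueError(
            f"sequence dimension {seq.shape[1]} does not match emission "
            f"dimension {params.n_features}"
        )
    logb = _emission_loglik(params, seq)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.startprob)
        loga = np.log(params.transmat)
    la = logpi + logb[0]
    for t in range(1, seq.shape[0]):
        la = logsumexp(la[:, None] + loga, axis=0) + logb[t]
    return float(logsumexp(la))


def _bakis_mask(q: int) -> np.ndarray:
    return np.triu(np.ones((q, q), dtype=bool))


class BakisGaussianHMM(BaseEstimator):
    """Left-right Gaussian HMM trained by multi-sequence Baum-Welch.

    Parameters
    ----------
    n_states
        Number of hidden states Q (default 3: loop, advance, skip).
    n_mix
        Gaussian components per state; only 1 is supported (the
        configuration under which the hybrid classifier performs best).
    max_iter, tol
        EM stops after ``max_iter`` iterations (default 1000) or when
        the total log-likelihood improves by less than ``tol``
        (default 0.01).
    var_floor
        Lower bound applied to emission variances.
    random_state
        Accepted for API symmetry; initialization is deterministic
        (pi = e_1, uniform allowed transitions, block-mean emission
        means), so the seed only matters for :meth:`sample`.

    Attributes
    ----------
    startprob_, transmat_, means_, variances_
        Fitted parameters (Bakis zeros exact).
    loglik_trace_
        Total log-likelihood before each EM update; non-decreasing.
    """

    def __init__(
        self,
        n_states: int = 3,
        n_mix: int = 1,
        max_iter: int = 1000,
        tol: float = 0.01,
        var_floor: float = 1e-6,
        random_state=None,
    ):
        self.n_states = n_states
        self.n_mix = n_mix
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor = var_floor
        self.random_state = random_state

    # -- initialization ----------------------------------------------

    def _validate_sequences(self, sequences):
        seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
        if not seqs:
            raise ValueError("no observation sequences given")
        d = seqs[0].shape[1]
        for s in seqs:
            if s.shape[1] != d:
                raise ValueError("sequences have inconsistent dimensions")
            if not np.all(np.isfinite(s)):
                raise ValueError("sequences contain non-finite features")
        total = sum(s.shape[0] for s in seqs)
        if total < self.n_states:
            raise ValueError(
                f"total frame count {total} is smaller than the number of "
                f"hidden states {self.n_states}"
            )
        return seqs, d

    def _initialize(self, seqs, d):
        q = self.n_states
        if self.n_mix != 1:
            raise ValueError(
                "only single-component Gaussian emissions are supported "
                f"(n_mix=1); got n_mix={self.n_mix}"
            )
        startprob = np.zeros(q)
        startprob[0] = 1.0
        mask = _bakis_mask(q)
        transmat = mask / mask.sum(axis=1, keepdims=True)
        # emission means: average of the q-th contiguous block over sequences
        sums = np.zeros((q, d))
        cnts = np.zeros(q)
        for s in seqs:
            for qi, block in enumerate(np.array_split(s, q)):
                if block.size:
                    sums[qi] += block.sum(axis=0)
                    cnts[qi] += block.shape[0]
        means = sums / np.maximum(cnts, 1.0)[:, None]
        allframes = np.concatenate(seqs, axis=0)
        pooled = np.maximum(allframes.var(axis=0), self.var_floor)
        variances = np.tile(pooled, (q, 1))
        return GaussianHMMParams(startprob, transmat, means, variances)

    # -- E-step (batched over equal-length sequences) -----------------

    @staticmethod
    def _forward_backward(params, batch):
        """Posteriors for a stack of equal-length sequences.

        batch: (S, T, D).  Returns (loglik_total, gamma (S,T,Q),
        xi_sum (Q,Q) summed over sequences and time).
        """
        S, T, _ = batch.shape
        q = params.n_states
        logb = np.stack(
            [_emission_loglik(params, batch[s]) for s in range(S)]
        )  # (S, T, Q)
        with np.errstate(divide="ignore"):
            logpi = np.log(params.startprob)
            loga = np.log(params.transmat)

        # log-domain recursions: robust to the huge emission log-density
        # gaps that high-dimensional diagonal Gaussians produce
        logalpha = np.empty((S, T, q))
        logalpha[:, 0] = logpi[None, :] + logb[:, 0]
        for t in range(1, T):
            logalpha[:, t] = (
                logsumexp(
                    logalpha[:, t - 1][:, :, None] + loga[None, :, :], axis=1
                )
                + logb[:, t]
            )
        ll_seq = logsumexp(logalpha[:, T - 1], axis=1)  # (S,)
        loglik = float(ll_seq.sum())

        logbeta = np.empty((S, T, q))
        logbeta[:, T - 1] = 0.0
        for t in range(T - 2, -1, -1):
            logbeta[:, t] = logsumexp(
                loga[None, :, :]
                + (logb[:, t + 1] + logbeta[:, t + 1])[:, None, :],
                axis=2,
            )

        gamma = np.exp(logalpha + logbeta - ll_seq[:, None, None])

        xi_sum = np.zeros((q, q))
        for t in range(T - 1):
            log_num = (
                logalpha[:, t][:, :, None]
                + loga[None, :, :]
                + (logb[:, t + 1] + logbeta[:, t + 1])[:, None, :]
                - ll_seq[:, None, None]
            )
            xi_sum += np.exp(log_num).sum(axis=0)
        return loglik, gamma, xi_sum

    # -- fitting ------------------------------------------------------

    def fit(self, sequences, y=None, callback=None):
        """Estimate parameters from a list of (T, D) sequences.

        ``callback(iteration, params, loglik)``, if given, is invoked
        after every EM update with a snapshot of the new parameters.
        """
        seqs, d = self._validate_sequences(sequences)
        params = self._initialize(seqs, d)
        mask = _bakis_mask(self.n_states)
        n_seq = len(seqs)

        # group sequences by length so the E-step is batched
        by_len: dict[int, list[int]] = {}
        for i, s in enumerate(seqs):
            by_len.setdefault(s.shape[0], []).append(i)
        batches = [
            np.stack([seqs[i] for i in idx]) for idx in by_len.values()
        ]

        trace: list[float] = []
        prev_ll = -np.inf
        for it in range(self.max_iter):
            total_ll = 0.0
            pi_acc = np.zeros(self.n_states)
            xi_acc = np.zeros((self.n_states, self.n_states))
            denom_acc = np.zeros(self.n_states)
            gsum = np.zeros(self.n_states)
            gx = np.zeros((self.n_states, d))
            gxx = np.zeros((self.n_states, d))
            for batch in batches:
                ll, gamma, xi_sum = self._forward_backward(params, batch)
                total_ll += ll
                pi_acc += gamma[:, 0].sum(axis=0)
                xi_acc += xi_sum
                denom_acc += gamma[:, :-1].sum(axis=(0, 1))
                gsum += gamma.sum(axis=(0, 1))
                flat_g = gamma.reshape(-1, self.n_states)
                flat_x = batch.reshape(-1, d)
                gx += flat_g.T @ flat_x
                gxx += flat_g.T @ (flat_x ** 2)
            trace.append(total_ll)

            # M-step
            startprob = pi_acc / n_seq
            startprob /= startprob.sum()
            transmat = np.array(params.transmat)
            for i in range(self.n_states):
                if denom_acc[i] > 0:
                    row = np.where(mask[i], xi_acc[i], 0.0)
                    s = row.sum()
                    if s > 0:
                        transmat[i] = row / s
            transmat[~mask] = 0.0
            means = np.array(params.means)
            variances = np.array(params.variances)
            occupied = gsum > 1e-12
            means[occupied] = gx[occupied] / gsum[occupied, None]
            variances[occupied] = np.maximum(
                gxx[occupied] / gsum[occupied, None] - means[occupied] ** 2,
                self.var_floor,
            )
            params = GaussianHMMParams(startprob, transmat, means, variances)
            if callback is not None:
                callback(it, params, total_ll)
            if total_ll - prev_ll < self.tol and it > 0:
                prev_ll = total_ll
                break
            prev_ll = total_ll

        self.params_ = params
        self.startprob_ = params.startprob
        self.transmat_ = params.transmat
        self.means_ = params.means
        self.variances_ = params.variances
        self.loglik_trace_ = trace
        self.n_iter_ = len(trace)
        return self

    # -- scoring and sampling -----------------------------------------

    def score(self, seq: np.ndarray) -> float:
        """log P(O | lambda) of one sequence."""
        return forward_loglik(self.params_, seq)

    def score_sequences(self, sequences) -> float:
        """Total log-likelihood of independent sequences (their sum)."""
        return float(sum(self.score(s) for s in sequences))

    def sample(self, n_sequences: int, length: int, random_state=None):
        """Draw sequences from the fitted (or preset) model."""
        rng = np.random.default_rng(
            random_state if random_state is not None else self.random_state
        )
        p = self.params_
        q, d = p.n_states, p.n_features
        out = np.empty((n_sequences, length, d))
        std = np.sqrt(p.variances)
        for s in range(n_sequences):
            state = rng.choice(q, p=p.startprob)
            for t in range(length):
                out[s, t] = p.means[state] + std[state] * rng.standard_normal(d)
                state = rng.choice(q, p=p.transmat[state])
        return out

    @classmethod
    def from_params(cls, params: GaussianHMMParams, **kwargs):
        """Wrap an explicit parameter set (no fitting)."""
        est = cls(n_states=params.n_states, **kwargs)
        est.params_ = params
        est.startprob_ = params.startprob
        est.transmat_ = params.transmat
        est.means_ = params.means
        est.variances_ = params.variances
        return est

    # -- persistence --------------------------------------------------

    def to_json(self, path: str) -> None:
        p = self.params_
        payload = {
            "startprob": p.startprob.tolist(),
            "transmat": p.transmat.tolist(),
            "means": p.means.tolist(),
            "variances": p.variances.tolist(),
            "n_states": p.n_states,
            "n_mix": self.n_mix,
            "n_features": p.n_features,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "BakisGaussianHMM":
        with open(path) as fh:
            payload = json.load(fh)
        params = GaussianHMMParams(
            np.array(payload["startprob"]),
            np.array(payload["transmat"]),
            np.array(payload["means"]),
            np.array(payload["variances"]),
        )
        return cls.from_params(params, n_mix=payload.get("n_mix", 1))


def classify(seq, model_high: BakisGaussianHMM, model_low: BakisGaussianHMM):
    """Max-likelihood decision between the high and low class models.

    Returns ``(label, scores)`` with ``label`` in {"high", "low"} and
    ``scores = (loglik_high, loglik_low)``.  A tie is broken toward
    "low" with a warning.
    """
    s_high = model_high.score(seq)
    s_low = model_low.score(seq)
    if s_high == s_low:
        warnings.warn(
            "high/low model log-likelihoods are tied; predicting 'low'",
            stacklevel=2,
        )
        return "low", (s_high, s_low)
    return ("high" if s_high > s_low else "low"), (s_high, s_low)


class HMMEmotionClassifier(BaseEstimator, ClassifierMixin):
    """Binary sequence classifier built from two per-class Bakis HMMs.

    ``fit`` takes a list of observation sequences and binary labels
    (0 = low, 1 = high), trains one :class:`BakisGaussianHMM` per class
    on that class's sequences, and ``predict`` assigns each sequence to
    the model with the larger forward log-likelihood (ties -> low).
    """

    def __init__(
        self,
        n_states: int = 3,
        n_mix: int = 1,
        max_iter: int = 1000,
        tol: float = 0.01,
        var_floor: float = 1e-6,
        random_state=None,
    ):
        self.n_states = n_states
        self.n_mix = n_mix
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor = var_floor
        self.random_state = random_state

    def _make_hmm(self):
        return BakisGaussianHMM(
            n_states=self.n_states,
            n_mix=self.n_mix,
            max_iter=self.max_iter,
            tol=self.tol,
            var_floor=self.var_floor,
            random_state=self.random_state,
        )

    def fit(self, sequences, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(
                "need both classes 0 (low) and 1 (high) in training labels; "
                f"got {classes.tolist()}"
            )
        self.models_ = {}
        for cls_label in (0, 1):
            cls_seqs = [s for s, lab in zip(sequences, y) if lab == cls_label]
            self.models_[cls_label] = self._make_hmm().fit(cls_seqs)
        self.classes_ = classes
        return self

    def decision_scores(self, sequences) -> np.ndarray:
        """(n, 2) array of (low, high) log-likelihoods per sequence."""
        return np.array(
            [
                [self.models_[0].score(s), self.models_[1].score(s)]
                for s in sequences
            ]
        )

    def predict(self, sequences) -> np.ndarray:
        scores = self.decision_scores(sequences)
        if np.any(scores[:, 0] == scores[:, 1]):
            warnings.warn(
                "tied log-likelihoods broken toward the low class",
                stacklevel=2,
            )
        # strict inequality: ties go to low
        return (scores[:, 1] > scores[:, 0]).astype(int)
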