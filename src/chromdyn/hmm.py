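"""K-state hidden Markov model with independent-Bernoulli mark emissions.

This is the ChromHMM model family: each hidden chromatin state k emits an
M-bit histone-mark presence vector o with probability
``prod_m p_km^o_m (1-p_km)^(1-o_m)``. Training is Baum-Welch EM over one
observation sequence per chromosome (adjacency is undefined across
chromosomes, so no transition spans a boundary); decoding is per-bin posterior
argmax by default, Viterbi optionally. Learned states are collapsed onto five
functional categories (promoter, enhancer, heterochromatin, repressed,
quiescent) by a rule cascade on the emission probabilities.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from ._constants import CATEGORIES, PROB_EPS
from .grid import BinGrid

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# model container
# --------------------------------------------------------------------------- #

@dataclass
class StateModel:
    """Parameters of the multivariate-Bernoulli HMM.

    States are numbered 1..K in user-facing tables; arrays are 0-indexed.
    """

    K: int
    initial: np.ndarray          # (K,) simplex
    transition: np.ndarray       # (K, K) row-stochastic
    emission: np.ndarray         # (K, M) Bernoulli probabilities
    mark_names: tuple
    log_likelihood: float | None = None
    category_of_state: dict | None = None   # state id (1-based) -> category
    training_history: list | None = None    # per-iteration log-likelihoods

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=np.float64)
        self.transition = np.asarray(self.transition, dtype=np.float64)
        self.emission = np.asarray(self.emission, dtype=np.float64)
        self.mark_names = tuple(self.mark_names)
        self.validate()

    def validate(self):
        K, M = self.K, len(self.mark_names)
        if self.initial.shape != (K,) or self.transition.shape != (K, K) \
                or self.emission.shape != (K, M):
            raise ValueError("parameter shapes inconsistent with K / marks")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution does not sum to 1")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows do not sum to 1")
        if np.any((self.emission < 0) | (self.emission > 1)):
            raise ValueError("emission probabilities outside [0,1]")
        if self.category_of_state is not None:
            bad = set(self.category_of_state.values()) - set(CATEGORIES)
            if bad:
                raise ValueError(f"unknown categories {bad}")
            if set(self.category_of_state) != set(range(1, K + 1)):
                raise ValueError("category_of_state must cover states 1..K")

    @property
    def n_marks(self) -> int:
        return len(self.mark_names)

    def categories_array(self) -> np.ndarray:
        if self.category_of_state is None:
            raise ValueError("states have not been collapsed to categories")
        return np.array([self.category_of_state[k + 1] for k in range(self.K)])

    def emission_table(self) -> pd.DataFrame:
        tab = pd.DataFrame(self.emission, columns=list(self.mark_names),
                           index=[f"E{k+1}" for k in range(self.K)])
        if self.category_of_state is not None:
            tab["category"] = self.categories_array()
        return tab

    # -- serialization -------------------------------------------------- #

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "mark_names": list(self.mark_names),
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
            "log_likelihood": self.log_likelihood,
            "category_of_state": (
                {str(k): v for k, v in self.category_of_state.items()}
                if self.category_of_state else None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateModel":
        cat = d.get("category_of_state")
        return cls(
            K=d["K"],
            initial=np.array(d["initial"]),
            transition=np.array(d["transition"]),
            emission=np.array(d["emission"]),
            mark_names=tuple(d["mark_names"]),
            log_likelihood=d.get("log_likelihood"),
            category_of_state={int(k): v for k, v in cat.items()} if cat else None,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StateModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------- #
# emission likelihoods
# --------------------------------------------------------------------------- #

def emission_logprob_matrix(obs: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """Log emission likelihoods, shape (T, K), for a (T, M) binary sequence."""
    obs = np.asarray(obs, dtype=np.float64)
    p = np.clip(emission, PROB_EPS, 1.0 - PROB_EPS)
    return obs @ np.log(p).T + (1.0 - obs) @ np.log1p(-p).T


def emission_loglik(observation: np.ndarray, state: int,
                    model: StateModel) -> float:
    """Log P(observation | state) for one M-bit vector (state is 1-based)."""
    logB = emission_logprob_matrix(np.asarray(observation)[None, :],
                                   model.emission)
    return float(logB[0, state - 1])


# --------------------------------------------------------------------------- #
# numba kernels: scaled forward-backward and Viterbi
# --------------------------------------------------------------------------- #

@njit(cache=True)
def _forward(B, pi, A):
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    return alpha, c


@njit(cache=True)
def _backward(B, A, c):
    T, K = B.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


@njit(cache=True)
def _xi_sum(alpha, beta, B, A, c):
    T, K = B.shape
    xi = np.zeros((K, K))
    for t in range(T - 1):
        w = B[t + 1] * beta[t + 1] / c[t + 1]
        for i in range(K):
            ai = alpha[t, i]
            for j in range(K):
                xi[i, j] += ai * A[i, j] * w[j]
    return xi


@njit(cache=True)
def _viterbi(logB, logpi, logA):
    T, K = logB.shape
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        nd = np.empty(K)
        for j in range(K):
            best, arg = -np.inf, 0
            for i in range(K):
                v = delta[i] + logA[i, j]
                if v > best:
                    best, arg = v, i
            nd[j] = best + logB[t, j]
            back[t, j] = arg
        delta = nd
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta)
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, np.max(delta)


def _prep_seq(seq):
    """Normalize a sequence to ``(mean_obs (T, M), n_replicates)``.

    A (T, M) array is a single observation sequence. An (R, T, M) array is R
    replicate sequences sharing one hidden state path (biological replicates of
    the same condition): because the Bernoulli log-likelihood is linear in the
    observations, the joint emission log-likelihood of R replicates equals
    ``R x logB(mean observation)``, so only the replicate mean and R are kept.
    """
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim == 2:
        return np.ascontiguousarray(seq), 1.0
    if seq.ndim == 3:
        return np.ascontiguousarray(seq.mean(axis=0)), float(seq.shape[0])
    raise ValueError("observation sequence must be (T, M) or (R, T, M)")


def _scaled_B(obs, emission, weight: float = 1.0):
    """Row-rescaled emission likelihood matrix and the log offset it absorbs."""
    logB = weight * emission_logprob_matrix(obs, emission)
    offset = logB.max(axis=1)
    B = np.exp(logB - offset[:, None])
    return B, offset


def forward_backward(obs: np.ndarray, model: StateModel):
    """Scaled forward-backward for one observation sequence.

    ``obs`` may be (T, M) or (R, T, M) replicate observations sharing one
    hidden path. Returns ``(log_likelihood, posteriors)`` with posteriors of
    shape (T, K) summing to 1 per bin. Raises if a non-finite value appears,
    naming the offending bin.
    """
    obs, weight = _prep_seq(np.atleast_2d(np.asarray(obs)))
    if obs.shape[0] == 0:
        raise ValueError("empty observation sequence")
    B, offset = _scaled_B(obs, model.emission, weight)
    alpha, c = _forward(B, model.initial, model.transition)
    if not np.all(np.isfinite(c)) or np.any(c <= 0):
        bad = int(np.flatnonzero(~np.isfinite(c) | (c <= 0))[0])
        raise FloatingPointError(f"forward scaling degenerate at bin {bad}")
    beta = _backward(B, model.transition, c)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    if not np.all(np.isfinite(gamma)):
        bad = int(np.flatnonzero(~np.isfinite(gamma).all(axis=1))[0])
        raise FloatingPointError(f"non-finite posterior at bin {bad}")
    loglik = float(np.log(c).sum() + offset.sum())
    return loglik, gamma


def sequences_loglik(seqs: Sequence[np.ndarray], model: StateModel) -> float:
    return sum(forward_backward(s, model)[0] for s in seqs)


# --------------------------------------------------------------------------- #
# Baum-Welch training
# --------------------------------------------------------------------------- #

def _random_init(K: int, M: int, rng: np.random.Generator) -> tuple:
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    # sticky prior on self-transitions: chromatin domains are contiguous
    A = 0.5 * A + 0.5 * np.eye(K)
    A /= A.sum(axis=1, keepdims=True)
    em = rng.uniform(0.1, 0.9, size=(K, M))
    return pi, A, em


def _kmeans_init(seqs, K: int, M: int, rng: np.random.Generator) -> tuple:
    """Data-driven initialization: k-means centroids of the observation
    vectors seed the emissions, placing each EM start near a basin where
    states already separate by mark combination."""
    from sklearn.cluster import KMeans

    rows = np.concatenate([obs for obs, _ in seqs])
    if len(rows) > 100_000:
        rows = rows[rng.choice(len(rows), 100_000, replace=False)]
    with warnings.catch_warnings():
        # fewer distinct patterns than K duplicates centroids; EM copes
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=K, n_init=3,
                    random_state=int(rng.integers(2**31))).fit(rows)
    em = np.clip(km.cluster_centers_, 0.05, 0.95)
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 0.1 / max(K - 1, 1)) + (0.9 - 0.1 / max(K - 1, 1)) * np.eye(K)
    A /= A.sum(axis=1, keepdims=True)
    return pi, A, em


def _em_fit(seqs, K, M, pi, A, em, max_iter, tol):
    history = []
    prev = -np.inf
    for _ in range(max_iter):
        pi_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        gw_acc = np.zeros(K)              # sum of gammas
        go_acc = np.zeros((K, M))         # gamma-weighted observations
        loglik = 0.0
        for obs, w in seqs:
            B, offset = _scaled_B(obs, em, w)
            alpha, c = _forward(B, pi, A)
            beta = _backward(B, A, c)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            loglik += float(np.log(c).sum() + offset.sum())
            pi_acc += gamma[0]
            xi_acc += _xi_sum(alpha, beta, B, A, c)
            # replicates weight the emission statistics, not the single path
            gw_acc += w * gamma.sum(axis=0)
            go_acc += w * (gamma.T @ obs)
        history.append(loglik)
        if loglik - prev < tol and np.isfinite(prev):
            prev = loglik
            break
        prev = loglik
        pi = pi_acc / pi_acc.sum()
        A = xi_acc / np.maximum(xi_acc.sum(axis=1, keepdims=True), 1e-300)
        em = np.clip(go_acc / np.maximum(gw_acc[:, None], 1e-300),
                     PROB_EPS, 1.0 - PROB_EPS)
    return pi, A, em, prev, history


def baum_welch_train(
    seqs: Sequence[np.ndarray],
    K: int,
    mark_names: Sequence[str] | None = None,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-3,
    n_restarts: int = 3,
    init_method: str = "auto",
) -> StateModel:
    """Fit the K-state Bernoulli HMM by EM over chromosome sequences.

    Every chromosome (and, in multi-timepoint designs, every
    (chromosome, timepoint) pair) is an independent observation sequence; all
    contribute jointly to one model. A sequence given as an (R, T, M) array is
    treated as R replicates sharing one hidden path. The best of
    ``n_restarts`` initializations (seeded, reproducible) is returned with its
    per-iteration log-likelihood history attached.

    ``init_method``: "auto" (default) seeds the first restart from k-means
    centroids of the observations and the rest randomly; "random" and
    "kmeans" force one strategy for every restart.
    """
    if init_method not in ("auto", "random", "kmeans"):
        raise ValueError(f"unknown init_method {init_method!r}")
    raw = [np.atleast_2d(np.asarray(s, dtype=np.float64)) for s in seqs]
    if not raw or any(s.shape[-2] == 0 for s in raw):
        raise ValueError("training requires non-empty observation sequences")
    seqs = [_prep_seq(s) for s in raw]
    M = seqs[0][0].shape[1]
    if K < 1:
        raise ValueError("K must be >= 1")
    packed = np.concatenate([s.reshape(-1, M) @ (1 << np.arange(M))
                             for s in raw])
    n_patterns = len(np.unique(packed))
    if K > n_patterns:
        warnings.warn(
            f"K={K} exceeds the {n_patterns} distinct observation patterns; "
            "some states will be redundant", stacklevel=2)
    if mark_names is None:
        mark_names = tuple(f"mark{j}" for j in range(M))

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        use_kmeans = (init_method == "kmeans"
                      or (init_method == "auto" and r == 0))
        if use_kmeans:
            pi0, A0, em0 = _kmeans_init(seqs, K, M, rng)
        else:
            pi0, A0, em0 = _random_init(K, M, rng)
        pi, A, em, ll, hist = _em_fit(seqs, K, M, pi0, A0, em0, max_iter, tol)
        if best is None or ll > best[3]:
            best = (pi, A, em, ll, hist)
    pi, A, em, ll, hist = best
    model = StateModel(K, pi, A, em, tuple(mark_names),
                       log_likelihood=ll, training_history=hist)
    return model


# --------------------------------------------------------------------------- #
# decoding
# --------------------------------------------------------------------------- #

@dataclass
class Segmentation:
    """Per-bin state assignment over a grid.

    ``states`` holds 1-based state ids; ``max_posterior`` the winning
    posterior probability per bin (1.0 under Viterbi decoding).
    """

    grid: BinGrid
    states: np.ndarray
    max_posterior: np.ndarray
    model: StateModel | None = None
    categories_override: np.ndarray | None = None   # for file round-trips

    def __post_init__(self):
        if self.states.shape != (self.grid.total_bins,):
            raise ValueError("segmentation length != grid bins")

    @property
    def categories(self) -> np.ndarray:
        if self.categories_override is not None:
            return self.categories_override
        cats = self.model.categories_array()
        return cats[self.states - 1]


def decode_sequences(seqs: Sequence[np.ndarray], model: StateModel,
                     method: str = "posterior"):
    """Decode sequences; returns (1-based states, max posterior) per sequence.

    Posterior argmax breaks ties toward the lower state id.
    """
    out = []
    for obs in seqs:
        obs = np.atleast_2d(np.asarray(obs, dtype=np.float64))
        if method == "posterior":
            _, gamma = forward_backward(obs, model)
            states = gamma.argmax(axis=1)
            out.append((states + 1, gamma[np.arange(len(states)), states]))
        elif method == "viterbi":
            mean_obs, w = _prep_seq(obs)
            logB = w * emission_logprob_matrix(mean_obs, model.emission)
            with np.errstate(divide="ignore"):
                logpi = np.log(np.maximum(model.initial, 1e-300))
                logA = np.log(np.maximum(model.transition, 1e-300))
            path, _ = _viterbi(logB, logpi, logA)
            out.append((path + 1, np.ones(len(path))))
        else:
            raise ValueError(f"unknown decode method {method!r}")
    return out


def decode(track_set, key, model: StateModel,
           method: str = "posterior") -> Segmentation:
    """Decode one sample of a :class:`~chromdyn.binarize.BinarizedTrackSet`.

    ``key`` may also be a list of keys (replicates of one condition), which
    are then decoded jointly under a shared hidden path.
    """
    if isinstance(key, list):
        seqs = track_set.grouped_sequences(key)
    else:
        seqs = track_set.sequences(key)
    parts = decode_sequences(seqs, model, method=method)
    states = np.concatenate([s for s, _ in parts])
    mp = np.concatenate([p for _, p in parts])
    return Segmentation(track_set.grid, states, mp, model=model)


# --------------------------------------------------------------------------- #
# model selection
# --------------------------------------------------------------------------- #

def n_free_parameters(K: int, M: int) -> int:
    """Free parameters of the K-state model: (K-1) + K(K-1) + K*M."""
    return (K - 1) + K * (K - 1) + K * M


def select_state_number(seqs: Sequence[np.ndarray], K_range: Sequence[int],
                        seed: int = 0, **fit_kwargs) -> pd.DataFrame:
    """Fit each K in ``K_range``; report log-likelihood and BIC.

    The choice of K is left to the user (the field's convention is to pick the
    smallest model that captures the mark interactions of interest); BIC is a
    guide, not a verdict.
    """
    if len(K_range) == 0:
        raise ValueError("K_range is empty")
    seqs = [np.atleast_2d(s) for s in seqs]
    n_obs = sum(s.shape[0] for s in seqs)
    M = seqs[0].shape[1]
    rows = []
    for K in K_range:
        model = baum_welch_train(seqs, K, seed=seed, **fit_kwargs)
        p = n_free_parameters(K, M)
        rows.append({"K": K, "log_likelihood": model.log_likelihood,
                     "n_params": p,
                     "BIC": -2.0 * model.log_likelihood + p * np.log(n_obs)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# category collapse
# --------------------------------------------------------------------------- #

def collapse_states(
    model_or_emission,
    mark_names: Sequence[str] | None = None,
    high: float = 0.5,
    promoter_mark: str = "H3K4me3",
    enhancer_marks: tuple = ("H3K4me1", "H3K27ac"),
    heterochromatin_mark: str = "H3K9me3",
    repressed_mark: str = "H3K27me3",
) -> dict:
    """Collapse learned states onto five categories by an emission rule cascade.

    With ``p`` a state's emission row and ``high`` the presence threshold
    (default 0.5):

    1. p[H3K4me3] high -> promoter (covers active and poised promoters,
       the latter also carrying H3K27me3);
    2. else p[H3K4me1] or p[H3K27ac] high -> enhancer (active, weak and
       poised/bivalent enhancers alike);
    3. else p[H3K9me3] high -> heterochromatin;
    4. else p[H3K27me3] high -> repressed;
    5. else quiescent.

    Returns ``{state_id (1-based): category}``; a pure function of the
    emissions, so permuting states permutes categories identically.
    """
    if isinstance(model_or_emission, StateModel):
        emission = model_or_emission.emission
        mark_names = model_or_emission.mark_names
    else:
        emission = np.asarray(model_or_emission)
        if mark_names is None:
            raise ValueError("mark_names required with a bare emission matrix")
    idx = {m: i for i, m in enumerate(mark_names)}
    for needed in (promoter_mark, *enhancer_marks, heterochromatin_mark,
                   repressed_mark):
        if needed not in idx:
            raise ValueError(f"mark {needed!r} absent from model")
    out = {}
    for k, p in enumerate(emission, start=1):
        if p[idx[promoter_mark]] >= high:
            out[k] = "promoter"
        elif any(p[idx[m]] >= high for m in enhancer_marks):
            out[k] = "enhancer"
        elif p[idx[heterochromatin_mark]] >= high:
            out[k] = "heterochromatin"
        elif p[idx[repressed_mark]] >= high:
            out[k] = "repressed"
        else:
            out[k] = "quiescent"
    if isinstance(model_or_emission, StateModel):
        model_or_emission.category_of_state = out
    return out


# --------------------------------------------------------------------------- #
# genomic-feature fold enrichment
# --------------------------------------------------------------------------- #

def feature_fold_enrichment(segmentation: Segmentation,
                            features: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Fold enrichment of each state on each genomic feature.

    ``FE(state, feature) = P(bin on feature | bin in state) / P(bin on feature)``.
    Features are interval frames with columns ``chrom, start, end``. A feature
    covering zero bins yields NaN for every state.
    """
    grid = segmentation.grid
    states = segmentation.states
    K = int(states.max())
    rows = {}
    for name, feat in features.items():
        mask = np.zeros(grid.total_bins, dtype=bool)
        for _, iv in feat.iterrows():
            if iv["chrom"] not in grid.chroms:
                continue
            lo, hi = grid.interval_bins(iv["chrom"], iv["start"], iv["end"])
            mask[lo:hi] = True
        base = mask.mean()
        col = np.full(K, np.nan)
        if base > 0:
            for k in range(1, K + 1):
                sel = states == k
                if sel.any():
                    col[k - 1] = mask[sel].mean() / base
                else:
                    col[k - 1] = np.nan
        else:
            logger.warning("feature %r covers zero bins; FE undefined", name)
        rows[name] = col
    return pd.DataFrame(rows, index=[f"E{k+1}" for k in range(K)])
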