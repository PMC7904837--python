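"""Per-condition stochastic trajectory models.

Two model families learn a discretized trajectory ensemble:

* :class:`TimeInhomogeneousMarkovModel` -- one column-stochastic transition matrix per
  consecutive timepoint pair, fitted by column-normalized transition counts (plus a
  pseudocount).  Flexible but parameter-hungry: one ``K_E x K_E`` matrix per step.
* :class:`HiddenMarkovModel` -- a time-homogeneous hidden-state chain with a single
  transition matrix ``T`` and emission matrix ``E``, fitted by Baum-Welch EM.  It
  captures history dependence (e.g. oscillations at varying frequency) with far fewer
  parameters.

Both families expose per-trajectory *prefix* log-probabilities ``log2 p(y_{1:n})`` for
``n = 1..N`` via the forward algorithm; these are the raw material of the trajectory
entropy and every information quantity downstream.

Matrix orientation: every stochastic matrix here is **column-stochastic** -- columns
index the conditioning variable (source state), so ``T[to, from]`` and
``E[symbol, hidden]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import DiscreteEnsemble, TrajectoryDataError

_LOG2 = np.log(2.0)


class ModelError(Exception):
    """Raised on invalid model construction or use."""


def _check_column_stochastic(mat: np.ndarray, name: str, atol: float = 1e-12) -> None:
    if np.any(mat < 0):
        raise ModelError(f"{name} has negative entries")
    sums = mat.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ModelError(f"{name} columns must sum to 1 (got {sums})")


@dataclass(frozen=True)
class TimeInhomogeneousMarkovModel:
    """One transition matrix per consecutive timepoint pair.

    ``transitions[t]`` is the column-stochastic matrix for the step from timepoint ``t``
    to ``t + 1``: entry ``(l', l)`` is ``p(y_{t+1} = l' | y_t = l)``.
    """

    initial: np.ndarray            # (K_E,) distribution at timepoint 1
    transitions: np.ndarray        # (N-1, K_E, K_E), column-stochastic
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        initial = np.asarray(self.initial, dtype=float)
        trans = np.asarray(self.transitions, dtype=float)
        if trans.ndim != 3 or trans.shape[1] != trans.shape[2]:
            raise ModelError("transitions must be (N-1, K, K)")
        if initial.shape != (trans.shape[1],):
            raise ModelError("initial length must match transition dimension")
        if not np.isclose(initial.sum(), 1.0, atol=1e-9) or np.any(initial < 0):
            raise ModelError("initial must be a probability vector")
        for t in range(trans.shape[0]):
            _check_column_stochastic(trans[t], f"transitions[{t}]")
        object.__setattr__(self, "initial", initial)
        object.__setattr__(self, "transitions", trans)

    @property
    def n_symbols(self) -> int:
        return self.initial.size

    @property
    def n_timepoints(self) -> int:
        return self.transitions.shape[0] + 1


@dataclass(frozen=True)
class HiddenMarkovModel:
    """Discrete-emission hidden Markov model.

    ``pi`` is the initial hidden-state distribution, ``T[to, from]`` the hidden
    transition matrix and ``E[symbol, hidden]`` the emission matrix; both are
    column-stochastic.  ``emission_floor`` records the floor applied to ``E`` after
    fitting so that no observed symbol has exactly zero likelihood under any
    condition's model.
    """

    pi: np.ndarray      # (K,)
    T: np.ndarray       # (K, K)
    E: np.ndarray       # (K_E, K)
    emission_floor: float = 0.0
    log_likelihood: float | None = None
    n_iter: int | None = None
    converged: bool | None = None

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        T = np.asarray(self.T, dtype=float)
        E = np.asarray(self.E, dtype=float)
        K = pi.size
        if T.shape != (K, K):
            raise ModelError("T must be (K, K)")
        if E.ndim != 2 or E.shape[1] != K:
            raise ModelError("E must be (K_E, K)")
        if not np.isclose(pi.sum(), 1.0, atol=1e-9) or np.any(pi < 0):
            raise ModelError("pi must be a probability vector")
        _check_column_stochastic(T, "T")
        _check_column_stochastic(E, "E")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "E", E)

    @property
    def n_hidden(self) -> int:
        return self.pi.size

    @property
    def n_symbols(self) -> int:
        return self.E.shape[0]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_time_inhomogeneous(
    ensemble: DiscreteEnsemble, pseudocount: float = 0.5
) -> TimeInhomogeneousMarkovModel:
    """Fit per-step transition matrices by column-normalized transition counts.

    For each consecutive timepoint pair the count matrix ``c(y_{t+1}, y_t)`` receives
    ``pseudocount`` in every cell and is then normalized by column; the initial
    distribution is the (pseudocounted) empirical distribution at timepoint 1.  A
    source state never visited at some step gets a uniform column (the pseudocount
    limit), keeping every matrix stochastic.
    """
    if pseudocount < 0:
        raise ModelError("pseudocount must be >= 0")
    Y = ensemble.states
    K = ensemble.n_symbols
    N = ensemble.n_timepoints
    if N < 2:
        raise ModelError("need >= 2 timepoints")
    trans = np.empty((N - 1, K, K))
    for t in range(N - 1):
        counts = np.zeros((K, K))
        np.add.at(counts, (Y[:, t + 1], Y[:, t]), 1.0)
        counts += pseudocount
        colsum = counts.sum(axis=0)
        empty = colsum == 0
        counts[:, empty] = 1.0 / K
        colsum[empty] = 1.0
        trans[t] = counts / colsum
    init = np.bincount(Y[:, 0], minlength=K).astype(float) + pseudocount
    if init.sum() == 0:
        init[:] = 1.0
    init /= init.sum()
    return TimeInhomogeneousMarkovModel(
        initial=init, transitions=trans, pseudocount=pseudocount
    )


def _random_stochastic(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Random column-stochastic matrix (independent flat Dirichlet columns)."""
    mat = rng.gamma(1.0, 1.0, size=shape)
    return mat / mat.sum(axis=0, keepdims=True)


def _baum_welch_once(
    Y: np.ndarray, K: int, K_E: int, rng: np.random.Generator,
    tol: float, max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, list[float]]:
    """One EM run from a random initialization; returns (pi, T, E, ll, n_iter, conv, trace).

    All sequences share one length, so the forward/backward passes are vectorized
    across the whole ensemble (arrays of shape (m, K) per timepoint).
    """
    m, N = Y.shape
    pi = rng.dirichlet(np.ones(K))
    T = _random_stochastic(rng, (K, K))
    E = _random_stochastic(rng, (K_E, K))

    ll_prev = -np.inf
    ll = -np.inf
    trace: list[float] = []
    converged = False
    n_iter = 0
    alphas = np.empty((N, m, K))
    cs = np.empty((N, m))
    for it in range(max_iter):
        # forward pass (scaled)
        A = pi[None, :] * E[Y[:, 0], :]
        c = A.sum(axis=1)
        c[c <= 0] = np.finfo(float).tiny
        A = A / c[:, None]
        alphas[0], cs[0] = A, c
        for t in range(1, N):
            A = E[Y[:, t], :] * (A @ T.T)
            c = A.sum(axis=1)
            c[c <= 0] = np.finfo(float).tiny
            A = A / c[:, None]
            alphas[t], cs[t] = A, c
        ll = float(np.log(cs).sum())
        trace.append(ll)
        n_iter = it + 1
        if ll - ll_prev < tol * abs(ll) and it > 0:
            converged = True
            break
        ll_prev = ll

        # backward pass + accumulators
        B = np.ones((m, K))
        gamma = alphas[N - 1] * B
        gamma /= gamma.sum(axis=1, keepdims=True)
        E_num = np.zeros((K_E, K))
        np.add.at(E_num, Y[:, N - 1], gamma)
        T_num = np.zeros((K, K))
        gamma0 = None
        for t in range(N - 1, 0, -1):
            Mt = (B * E[Y[:, t], :]) / cs[t][:, None]          # (m, to)
            T_num += (Mt.T @ alphas[t - 1]) * T                 # (to, from)
            B = Mt @ T                                          # beta_{t-1}, (m, from)
            gamma = alphas[t - 1] * B
            gamma /= gamma.sum(axis=1, keepdims=True)
            np.add.at(E_num, Y[:, t - 1], gamma)
            if t == 1:
                gamma0 = gamma
        # M-step
        pi = gamma0.mean(axis=0)
        pi = pi / pi.sum()
        colsum = T_num.sum(axis=0)
        dead = colsum <= 0
        T_num[:, dead] = 1.0
        T = T_num / T_num.sum(axis=0, keepdims=True)
        colsum = E_num.sum(axis=0)
        dead = colsum <= 0
        E_num[:, dead] = 1.0
        E = E_num / E_num.sum(axis=0, keepdims=True)
    return pi, T, E, ll, n_iter, converged, trace


def fit_hmm(
    ensemble: DiscreteEnsemble,
    n_hidden: int,
    restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    emission_floor: float = 1e-6,
) -> HiddenMarkovModel:
    """Baum-Welch maximum-likelihood fit over all trajectories jointly.

    Among ``restarts`` seeded random initializations the parameter set with the highest
    total log-likelihood is kept.  Convergence: relative log-likelihood improvement
    below ``tol`` (or ``max_iter`` reached).  After EM the emission matrix is floored
    at ``emission_floor`` and renormalized, so no symbol of the shared alphabet ever
    has exactly zero likelihood -- required when one condition's model scores another
    condition's trajectories.
    """
    if ensemble.n_symbols < 2:
        raise ModelError("emission alphabet must have >= 2 symbols")
    if n_hidden < 1:
        raise ModelError("need >= 1 hidden state")
    Y = ensemble.states
    best = None
    rng = np.random.default_rng(seed)
    for _ in range(max(1, restarts)):
        out = _baum_welch_once(Y, n_hidden, ensemble.n_symbols, rng, tol, max_iter)
        if best is None or out[3] > best[3]:
            best = out
    pi, T, E, ll, n_iter, converged, _ = best
    if emission_floor > 0:
        E = np.maximum(E, emission_floor)
        E = E / E.sum(axis=0, keepdims=True)
    return HiddenMarkovModel(
        pi=pi, T=T, E=E, emission_floor=emission_floor,
        log_likelihood=ll, n_iter=n_iter, converged=converged,
    )


# ---------------------------------------------------------------------------
# Prefix log-probabilities (forward algorithm)
# ---------------------------------------------------------------------------

def _as_state_matrix(trajectories: np.ndarray) -> np.ndarray:
    Y = np.asarray(trajectories)
    if Y.ndim == 1:
        Y = Y[None, :]
    return Y.astype(np.int64)


def hmm_prefix_log_probs_matrix(model: HiddenMarkovModel, trajectories: np.ndarray) -> np.ndarray:
    """``log2 p(y_{1:n})`` for every trajectory and prefix length, shape (m, N).

    Scaled forward recursion: the joint prefix probability over hidden states,
    ``p(y_{1:n}, x_n) = E(y_n|x_n) sum_{x_{n-1}} T(x_n|x_{n-1}) p(y_{1:n-1}, x_{n-1})``,
    is renormalized each step and the log scaling factors accumulated, so trajectories
    of hundreds of timepoints do not underflow.
    """
    Y = _as_state_matrix(trajectories)
    if Y.size and (Y.min() < 0 or Y.max() >= model.n_symbols):
        raise ModelError("trajectory contains symbols outside the model alphabet")
    m, N = Y.shape
    out = np.empty((m, N))
    with np.errstate(divide="ignore"):
        A = model.pi[None, :] * model.E[Y[:, 0], :]
        c = A.sum(axis=1)
        out[:, 0] = np.log2(c)
        safe = np.where(c > 0, c, 1.0)
        A = np.where(c[:, None] > 0, A / safe[:, None], 1.0 / model.n_hidden)
        for t in range(1, N):
            A = model.E[Y[:, t], :] * (A @ model.T.T)
            c = A.sum(axis=1)
            out[:, t] = out[:, t - 1] + np.log2(c)
            safe = np.where(c > 0, c, 1.0)
            A = np.where(c[:, None] > 0, A / safe[:, None], 1.0 / model.n_hidden)
    return out


def timm_prefix_log_probs_matrix(
    model: TimeInhomogeneousMarkovModel, trajectories: np.ndarray
) -> np.ndarray:
    """``log2 p(y_{1:n})`` under the time-inhomogeneous chain, shape (m, N)."""
    Y = _as_state_matrix(trajectories)
    if Y.size and (Y.min() < 0 or Y.max() >= model.n_symbols):
        raise ModelError("trajectory contains symbols outside the model alphabet")
    m, N = Y.shape
    if N > model.n_timepoints:
        raise ModelError(
            f"trajectory length {N} exceeds model horizon {model.n_timepoints}"
        )
    steps = np.empty((m, N))
    with np.errstate(divide="ignore"):
        steps[:, 0] = np.log2(model.initial[Y[:, 0]])
        for t in range(1, N):
            steps[:, t] = np.log2(model.transitions[t - 1][Y[:, t], Y[:, t - 1]])
    out = np.cumsum(steps, axis=1)
    if np.isneginf(out).any():
        warnings.warn(
            "zero-probability step encountered; prefix log-probabilities are -inf "
            "from that point on (fit with a positive pseudocount to avoid this)",
            RuntimeWarning,
        )
    return out


def forward_prefix_log_probs(model: HiddenMarkovModel, trajectory: np.ndarray) -> np.ndarray:
    """Prefix log2-probabilities of a single trajectory under an HMM."""
    return hmm_prefix_log_probs_matrix(model, np.asarray(trajectory))[0]


def timm_prefix_log_probs(
    model: TimeInhomogeneousMarkovModel, trajectory: np.ndarray
) -> np.ndarray:
    """Prefix log2-probabilities of a single trajectory under the Markov chain."""
    return timm_prefix_log_probs_matrix(model, np.asarray(trajectory))[0]


def prefix_log_probs_matrix(model, trajectories: np.ndarray) -> np.ndarray:
    """Family-dispatching prefix scorer (HMM or time-inhomogeneous Markov)."""
    if isinstance(model, HiddenMarkovModel):
        return hmm_prefix_log_probs_matrix(model, trajectories)
    if isinstance(model, TimeInhomogeneousMarkovModel):
        return timm_prefix_log_probs_matrix(model, trajectories)
    raise ModelError(f"unsupported model type {type(model).__name__}")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_categorical_cols(
    cum: np.ndarray, idx: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Vectorized draw: row r sampled from the column ``idx[r]`` of cumsum matrix."""
    rows = cum.T[idx]                       # (n, n_outcomes) cumulative probabilities
    return (rows < u[:, None]).sum(axis=1)


def sample_model(
    model: HiddenMarkovModel | TimeInhomogeneousMarkovModel,
    n_traj: int,
    length: int,
    seed: int = 0,
    condition_label: str = "sample",
    scheme_id: str | None = None,
) -> DiscreteEnsemble:
    """Ancestral sampling of ``n_traj`` trajectories of ``length`` timepoints."""
    rng = np.random.default_rng(seed)
    if isinstance(model, HiddenMarkovModel):
        K, K_E = model.n_hidden, model.n_symbols
        cumT = np.cumsum(model.T, axis=0)
        cumE = np.cumsum(model.E, axis=0)
        cum_pi = np.cumsum(model.pi)
        Y = np.empty((n_traj, length), dtype=np.int64)
        x = (cum_pi < rng.random(n_traj)[:, None]).sum(axis=1)
        Y[:, 0] = _sample_categorical_cols(cumE, x, rng.random(n_traj))
        for t in range(1, length):
            x = _sample_categorical_cols(cumT, x, rng.random(n_traj))
            Y[:, t] = _sample_categorical_cols(cumE, x, rng.random(n_traj))
        n_symbols = K_E
    elif isinstance(model, TimeInhomogeneousMarkovModel):
        if length > model.n_timepoints:
            raise ModelError(
                f"length {length} exceeds model horizon {model.n_timepoints}"
            )
        K = model.n_symbols
        Y = np.empty((n_traj, length), dtype=np.int64)
        cum_init = np.cumsum(model.initial)
        Y[:, 0] = (cum_init < rng.random(n_traj)[:, None]).sum(axis=1)
        for t in range(1, length):
            cumP = np.cumsum(model.transitions[t - 1], axis=0)
            Y[:, t] = _sample_categorical_cols(cumP, Y[:, t - 1], rng.random(n_traj))
        n_symbols = K
    else:
        raise ModelError(f"unsupported model type {type(model).__name__}")
    return DiscreteEnsemble(
        condition_label=condition_label, states=Y, n_symbols=n_symbols,
        scheme_id=scheme_id,
    )


# ---------------------------------------------------------------------------
# Configuration used by the workflow layers
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """How to fit one per-condition model; shared across conditions in a run.

    ``n_hidden`` defaults to twice the emission alphabet size (the 2:1
    hidden:emission ratio used throughout).
    """

    family: str = "hmm"                 # "hmm" | "markov"
    n_hidden: int | None = None
    pseudocount: float = 0.5
    restarts: int = 5
    tol: float = 1e-6
    max_iter: int = 500
    emission_floor: float = 1e-6

    def resolve_hidden(self, n_symbols: int) -> int:
        return self.n_hidden if self.n_hidden is not None else 2 * n_symbols

    def fit(self, ensemble: DiscreteEnsemble, seed: int = 0):
        if self.family == "hmm":
            return fit_hmm(
                ensemble,
                n_hidden=self.resolve_hidden(ensemble.n_symbols),
                restarts=self.restarts,
                tol=self.tol,
                max_iter=self.max_iter,
                seed=seed,
                emission_floor=self.emission_floor,
            )
        if self.family == "markov":
            return fit_time_inhomogeneous(ensemble, pseudocount=self.pseudocount)
        raise ModelError(f"unknown model family {self.family!r}")
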