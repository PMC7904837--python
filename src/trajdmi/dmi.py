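"""Trajectory-space mutual information between stimulus conditions and responses.

Given per-condition generative models and the trajectory ensembles they were fitted
on, the dynamical mutual information (dMI) up to timepoint ``n`` is

    I(R_{1:n}; S) = H(R_{1:n}) - H(R_{1:n} | S)

where the conditional trajectory entropy averages, over the trajectories of each
condition, the trajectory entropy ``-log2 p(y_{1:n} | S = i)`` under that condition's
own model, and the unconditional entropy replaces the self-conditioned probability by
the stimulus-weighted mixture ``sum_k q_k p(y_{1:n} | S = k)``.  The *maximum* dMI
maximizes this plug-in estimate over the stimulus-weight distribution ``q`` on the
probability simplex (a concave problem), at each cumulative timepoint; it approximates
the capacity of the signaling channel restricted to the supplied condition set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import DiscreteEnsemble
from .models import prefix_log_probs_matrix

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)


class DMIError(Exception):
    pass


class ConvergenceError(DMIError):
    """Simplex maximization failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best_value: float, best_q: np.ndarray):
        super().__init__(message)
        self.best_value = best_value
        self.best_q = best_q


def trajectory_entropy(log2_prob: float) -> float:
    """Entropy of a single trajectory, ``-log2 p(y_{1:n})`` in bits."""
    if np.any(np.asarray(log2_prob) > 0):
        raise DMIError("log2 probability must be <= 0")
    return -log2_prob


@dataclass(frozen=True)
class StimulusWeights:
    """Probability vector q over the M stimulus conditions."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1:
            raise DMIError("q must be a vector")
        if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-10:
            raise DMIError("q must be non-negative and sum to 1")
        object.__setattr__(self, "q", q)

    @property
    def n_conditions(self) -> int:
        return self.q.size

    @staticmethod
    def uniform(M: int) -> "StimulusWeights":
        return StimulusWeights(np.full(M, 1.0 / M))


@dataclass(frozen=True)
class ConditionScores:
    """All-vs-all prefix log-probabilities.

    ``scores[i]`` has shape (m_i, M, N): trajectory j of condition i scored under
    condition k's model at prefix length n is ``scores[i][j, k, n-1]`` (log2).  The
    diagonal slice (k = i) uses the model trained on condition i itself.
    """

    labels: tuple[str, ...]
    scores: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        M = len(self.labels)
        if len(self.scores) != M:
            raise DMIError("one score array per condition required")
        N = self.scores[0].shape[2]
        for i, s in enumerate(self.scores):
            if s.ndim != 3 or s.shape[1] != M or s.shape[2] != N:
                raise DMIError(f"scores[{i}] must be (m_i, {M}, {N})")
            if not np.all(np.isfinite(s)):
                raise DMIError(
                    f"scores[{i}] contains non-finite values; fit models with a "
                    "positive emission floor / pseudocount"
                )
            if np.any(s > 1e-9):
                raise DMIError(f"scores[{i}] contains positive log-probabilities")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "scores", tuple(np.asarray(s) for s in self.scores))

    @property
    def n_conditions(self) -> int:
        return len(self.labels)

    @property
    def n_timepoints(self) -> int:
        return self.scores[0].shape[2]

    def at(self, n: int) -> list[np.ndarray]:
        """Per-condition (m_i, M) log2 score slices at prefix length ``n`` (1-based)."""
        if not 1 <= n <= self.n_timepoints:
            raise DMIError(f"timepoint n={n} outside 1..{self.n_timepoints}")
        return [s[:, :, n - 1] for s in self.scores]


def score_conditions(models: list, ensembles: list[DiscreteEnsemble]) -> ConditionScores:
    """Score every trajectory of every condition under every condition's model.

    All models must belong to one family and all ensembles must share one
    discretization (same alphabet, same scheme id); mixing is rejected because the
    resulting likelihoods would not be comparable.
    """
    if len(models) != len(ensembles) or not models:
        raise DMIError("need one model per condition")
    fam = type(models[0])
    if any(type(m) is not fam for m in models):
        raise DMIError("all conditions must use the same model family")
    if len({m.n_symbols for m in models}) != 1:
        raise DMIError("models disagree on the emission alphabet size")
    scheme_ids = {e.scheme_id for e in ensembles}
    if len(scheme_ids) != 1:
        raise DMIError(
            f"ensembles were discretized under different schemes: {scheme_ids}"
        )
    if len({e.n_symbols for e in ensembles}) != 1:
        raise DMIError("ensembles disagree on the alphabet size")
    labels = tuple(e.condition_label for e in ensembles)
    scores = []
    for ens in ensembles:
        per_model = [prefix_log_probs_matrix(m, ens.states) for m in models]
        scores.append(np.stack(per_model, axis=1))      # (m_i, M, N)
    return ConditionScores(labels=labels, scores=tuple(scores))


# ---------------------------------------------------------------------------
# Entropies and dMI at a fixed timepoint
# ---------------------------------------------------------------------------

def _slices_and_weights(scores: ConditionScores, n: int):
    S_list = scores.at(n)
    w_list = [np.full(S.shape[0], 1.0 / S.shape[0]) for S in S_list]
    return S_list, w_list


def _log2_mixture(S: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Stable ``log2 sum_k q_k 2^{S[., k]}``; exact-zero weights are dropped."""
    mask = q > 0
    with np.errstate(divide="ignore"):
        logq = np.log2(q[mask])
    return logsumexp((S[:, mask] + logq[None, :]) * _LN2, axis=1) / _LN2

def conditional_entropy(scores: ConditionScores, q: StimulusWeights, n: int) -> float:
    """H(R_{1:n} | S): q-weighted mean self-model trajectory entropy, in bits."""
    S_list, w_list = _slices_and_weights(scores, n)
    total = 0.0
    for i, (S, w) in enumerate(zip(S_list, w_list)):
        total -= q.q[i] * float(w @ S[:, i])
    return total


def unconditional_entropy(scores: ConditionScores, q: StimulusWeights, n: int) -> float:
    """H(R_{1:n}): mean trajectory entropy under the q-weighted model mixture, bits."""
    S_list, w_list = _slices_and_weights(scores, n)
    total = 0.0
    for i, (S, w) in enumerate(zip(S_list, w_list)):
        if q.q[i] == 0:
            continue
        total -= q.q[i] * float(w @ _log2_mixture(S, q.q))
    return total


def dmi(scores: ConditionScores, q: StimulusWeights, n: int) -> float:
    """dMI in bits at prefix length ``n`` for stimulus weights ``q``.

    Clipped at 0 from below; a raw value below -1e-9 (which finite-sample estimates
    can produce only through numerical trouble) is logged before clipping.
    """
    raw = unconditional_entropy(scores, q, n) - conditional_entropy(scores, q, n)
    if raw < -1e-9:
        logger.warning("dMI estimate %.3e bits below zero at n=%d; clipping", raw, n)
    return max(raw, 0.0)


# ---------------------------------------------------------------------------
# Maximization over the stimulus-weight simplex
# ---------------------------------------------------------------------------

def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of v onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    idx = np.arange(1, v.size + 1)
    rho = np.nonzero(u * idx > (css - 1.0))[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _objective_and_grad(q, S_list, w_list):
    """Plug-in MI (bits) and its gradient on the simplex.

    I(q) = sum_i q_i sum_j w_ij [ S_i[j, i] - log2 sum_k q_k 2^{S_i[j, k]} ].
    This covers both the trajectory-sample estimate (w_ij = 1/m_i) and an exact
    discrete memoryless channel (j indexes symbols, w_ij = p(y_j | i)).
    """
    M = q.size
    I = 0.0
    grad = np.zeros(M)
    for i, (S, w) in enumerate(zip(S_list, w_list)):
        G = _log2_mixture(S, q)                     # (m_i,)
        a_i = float(w @ S[:, i])
        b_i = float(w @ G)
        I += q[i] * (a_i - b_i)
        grad[i] += a_i - b_i
        R = np.exp2(S - G[:, None])                 # likelihood ratios vs mixture
        grad -= (q[i] / _LN2) * (w @ R)
    return I, grad


def _maximize_on_simplex(
    S_list, w_list, tol: float = 1e-6, max_iter: int = 10_000
) -> tuple[float, np.ndarray]:
    """Projected-gradient ascent with backtracking for the concave MI objective.

    Starts from uniform q, so the returned value never falls below the uniform-weight
    MI.  Converged when an accepted step improves the objective by less than ``tol``
    bits.
    """
    M = len(S_list)
    q = np.full(M, 1.0 / M)
    I, g = _objective_and_grad(q, S_list, w_list)
    step = 1.0
    for _ in range(max_iter):
        accepted = False
        while step > 1e-18:
            q_new = _project_simplex(q + step * g)
            d = q_new - q
            if np.abs(d).max() == 0.0:
                return I, q            # stationary: projection does not move
            I_new, g_new = _objective_and_grad(q_new, S_list, w_list)
            if I_new >= I + 1e-4 * float(g @ d):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            return I, q                # no ascent direction at numerical precision
        improved = I_new - I
        q, I, g = q_new, I_new, g_new
        step = min(step * 2.0, 1e6)
        if improved < tol:
            return I, q
    raise ConvergenceError(
        f"simplex maximization did not converge within {max_iter} iterations",
        best_value=I, best_q=q,
    )


def maximize_dmi(
    scores: ConditionScores, n: int, tol: float = 1e-6
) -> tuple[float, StimulusWeights]:
    """Maximum dMI (bits) over stimulus weights at prefix length ``n``."""
    if scores.n_conditions < 2:
        raise DMIError("need M >= 2 conditions to maximize the dMI")
    S_list, w_list = _slices_and_weights(scores, n)
    I, q = _maximize_on_simplex(S_list, w_list, tol=tol)
    return max(I, 0.0), StimulusWeights(q)


# ---------------------------------------------------------------------------
# Cumulative curve, permutation control, single-timepoint baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DMICurve:
    """Maximum dMI per cumulative timepoint, with the optimal weights at each n.

    The curve is *not* necessarily monotone in n: the plug-in estimate can dip when an
    intermediate phase of the responses is less condition-specific.
    """

    timepoints: np.ndarray        # 1..N
    max_dmi: np.ndarray           # bits
    uniform_dmi: np.ndarray       # bits, at uniform q
    optimal_q: np.ndarray         # (N, M)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        M = len(self.labels)
        if np.any(self.max_dmi < -1e-9) or np.any(self.max_dmi > np.log2(M) + 1e-9):
            raise DMIError("max dMI outside [0, log2 M]")
        if np.any(self.max_dmi < self.uniform_dmi - 1e-9):
            raise DMIError("maximized dMI fell below the uniform-weight dMI")

    @property
    def final_max_dmi(self) -> float:
        return float(self.max_dmi[-1])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({
            "timepoint": self.timepoints,
            "max_dmi_bits": self.max_dmi,
            "uniform_dmi_bits": self.uniform_dmi,
        })
        for k, lbl in enumerate(self.labels):
            df[f"q_{lbl}"] = self.optimal_q[:, k]
        return df

    def save(self, path, metadata: dict | None = None) -> None:
        """Write the curve as delimited text plus a YAML run-metadata sidecar."""
        from pathlib import Path
        import yaml

        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if metadata is not None:
            with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
                yaml.safe_dump(metadata, fh, sort_keys=False)


def dmi_curve_from_scores(scores: ConditionScores, tol: float = 1e-6) -> DMICurve:
    """Maximize the dMI independently at every cumulative timepoint."""
    N, M = scores.n_timepoints, scores.n_conditions
    max_dmi = np.empty(N)
    uniform = np.empty(N)
    qs = np.empty((N, M))
    u = StimulusWeights.uniform(M)
    for n in range(1, N + 1):
        I, qstar = maximize_dmi(scores, n, tol=tol)
        max_dmi[n - 1] = min(I, np.log2(M))
        qs[n - 1] = qstar.q
        uniform[n - 1] = dmi(scores, u, n)
    return DMICurve(
        timepoints=np.arange(1, N + 1), max_dmi=max_dmi, uniform_dmi=uniform,
        optimal_q=qs, labels=scores.labels,
    )


def dmi_curve(models: list, ensembles: list[DiscreteEnsemble], tol: float = 1e-6) -> DMICurve:
    """Score all conditions once, then maximize the dMI at each timepoint."""
    return dmi_curve_from_scores(score_conditions(models, ensembles), tol=tol)


def permute_timepoints(ensembles: list, seed: int = 0):
    """Apply one random permutation of the timepoint columns to every ensemble.

    The same permutation is used for all conditions (and is returned for audit), so
    per-timepoint marginals are preserved exactly while temporal ordering is
    destroyed -- the control demonstrating that the dMI draws on dynamics, not just
    amplitude statistics.
    """
    from dataclasses import replace

    lengths = {e.states.shape[1] if isinstance(e, DiscreteEnsemble) else e.values.shape[1]
               for e in ensembles}
    if len(lengths) != 1:
        raise DMIError(f"ensembles have mismatched timepoint counts: {lengths}")
    (N,) = lengths
    perm = np.random.default_rng(seed).permutation(N)
    out = []
    for e in ensembles:
        if isinstance(e, DiscreteEnsemble):
            out.append(replace(e, states=e.states[:, perm]))
        else:
            out.append(replace(e, values=e.values[:, perm]))
    return out, perm


def timepoint_mi(
    ensembles: list[DiscreteEnsemble], n: int, pseudocount: float = 0.5,
    tol: float = 1e-6,
) -> tuple[float, StimulusWeights]:
    """Single-timepoint baseline: maximum MI of the symbol distributions at column n.

    The per-condition empirical symbol distributions at timepoint ``n`` (1-based,
    pseudocounted) define a discrete memoryless channel whose input weights are
    maximized with the same simplex optimizer as the dMI.  This is the classic
    timepoint method; it ignores all temporal structure.
    """
    if len({e.n_symbols for e in ensembles}) != 1:
        raise DMIError("ensembles disagree on the alphabet size")
    K = ensembles[0].n_symbols
    M = len(ensembles)
    P = np.empty((K, M))
    for k, e in enumerate(ensembles):
        counts = np.bincount(e.states[:, n - 1], minlength=K).astype(float)
        counts += pseudocount
        P[:, k] = counts / counts.sum()
    with np.errstate(divide="ignore"):
        logP = np.log2(P)
    S_list = [logP for _ in range(M)]        # rows = symbols, cols = conditions
    w_list = [P[:, i] for i in range(M)]
    I, q = _maximize_on_simplex(S_list, w_list, tol=tol)
    return max(I, 0.0), StimulusWeights(q)
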