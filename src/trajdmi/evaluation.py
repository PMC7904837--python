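"""Model-quality metrics and the split-half overfitting check.

Three training-performance measures mirror standard practice for generative models of
trajectory ensembles:

* **relative KL-divergence** -- per-timepoint KL between the data's and the model
  sample's symbol marginals, divided by the data marginal's entropy; below ~0.1 means
  the model reproduces the per-timepoint statistics to within a tenth of their
  information content.
* **false k-nearest-neighbor probability** -- mix model-sampled and measured
  trajectories, count cross-ensemble members among each sampled trajectory's k nearest
  neighbors, and fit the count histogram to a binomial law; a fitted probability of
  0.5 indicates perfect mixing (sample indistinguishable from data).
* **rescaled log-likelihood** -- held-out per-step log-likelihood ratio against a
  uniform-emission null, so the score does not trivially decay with alphabet size;
  positive values mean the model beats the null.

Overfitting is detected by the split-half protocol: the maximum dMI between two random
halves of one condition's ensemble should be near zero (both halves obey the same law);
it rises above zero when the models memorize their half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .data import DiscreteEnsemble, TrajectoryEnsemble, subset_rows
from .models import ModelConfig, prefix_log_probs_matrix, sample_model

_LN2 = np.log(2.0)


class EvaluationError(Exception):
    pass


def _marginal(states_col: np.ndarray, n_symbols: int, pseudocount: float) -> np.ndarray:
    counts = np.bincount(states_col, minlength=n_symbols).astype(float) + pseudocount
    return counts / counts.sum()


def relative_kl_per_timepoint(
    data: DiscreteEnsemble, sample: DiscreteEnsemble, pseudocount: float = 0.5
) -> tuple[np.ndarray, float]:
    """KL(data || sample) / H(data) per timepoint (base 2), and the mean over time.

    Both marginals receive ``pseudocount`` per symbol before normalization, so the
    ratio is defined even for symbols absent at some timepoint.  A timepoint with zero
    data entropy (impossible once pseudocounted with >= 2 symbols) would report 0 when
    its KL is 0 and be excluded from the mean otherwise.
    """
    if data.n_symbols != sample.n_symbols:
        raise EvaluationError("data and sample must share one alphabet")
    if data.n_timepoints != sample.n_timepoints:
        raise EvaluationError("data and sample must share the timepoint count")
    N, K = data.n_timepoints, data.n_symbols
    ratios = np.empty(N)
    valid = np.ones(N, dtype=bool)
    for t in range(N):
        p = _marginal(data.states[:, t], K, pseudocount)
        q = _marginal(sample.states[:, t], K, pseudocount)
        nz = p > 0
        kl = float(np.sum(p[nz] * (np.log2(p[nz]) - np.log2(q[nz]))))
        h = float(-np.sum(p[nz] * np.log2(p[nz])))
        if h > 0:
            ratios[t] = kl / h
        elif kl == 0:
            ratios[t] = 0.0
        else:
            ratios[t] = np.nan
            valid[t] = False
    mean = float(ratios[valid].mean())
    return ratios, mean


def _as_vectors(ensemble) -> np.ndarray:
    if isinstance(ensemble, TrajectoryEnsemble):
        return ensemble.values.astype(float)
    if isinstance(ensemble, DiscreteEnsemble):
        return ensemble.states.astype(float)
    return np.asarray(ensemble, dtype=float)


def false_knn_probability(
    data, sample, k_values: tuple[int, ...] = (1, 5, 10), seed: int = 0
) -> tuple[float, dict[int, float]]:
    """Fitted binomial mixing probability of sample trajectories in the mixed pool.

    Trajectories are embedded as their full-length value vectors (continuous values
    when available, else state indices).  For each trajectory of ``sample``, the
    number of its k nearest Euclidean neighbors (self excluded) belonging to ``data``
    ("false" neighbors) is counted; the maximum-likelihood binomial fit of the count
    histogram is ``p_hat = mean(count) / k``.  Returns the mean over ``k_values`` and
    the per-k detail.  The seed shuffles the pooled ordering, making distance-tie
    resolution deterministic.
    """
    Xd = _as_vectors(data)
    Xs = _as_vectors(sample)
    if Xd.shape[1] != Xs.shape[1]:
        raise EvaluationError("both ensembles must share the trajectory length")
    max_k = max(k_values)
    pool = np.vstack([Xd, Xs])
    if max_k >= pool.shape[0]:
        raise EvaluationError(
            f"k={max_k} must be below the pooled trajectory count {pool.shape[0]}"
        )
    is_data = np.zeros(pool.shape[0], dtype=bool)
    is_data[: Xd.shape[0]] = True
    order = np.random.default_rng(seed).permutation(pool.shape[0])
    pool, is_data = pool[order], is_data[order]
    query_idx = np.nonzero(~is_data)[0]

    nn = NearestNeighbors(n_neighbors=max_k + 1).fit(pool)
    _, idx = nn.kneighbors(pool[query_idx])
    # drop self from each neighbor list (guard against ties displacing it)
    neighbors = np.empty((query_idx.size, max_k), dtype=int)
    for r, qi in enumerate(query_idx):
        row = idx[r]
        row = row[row != qi][:max_k]
        neighbors[r] = row
    per_k: dict[int, float] = {}
    for k in k_values:
        counts = is_data[neighbors[:, :k]].sum(axis=1)
        per_k[k] = float(counts.mean() / k)
    return float(np.mean(list(per_k.values()))), per_k


def rescaled_log_likelihood(model, test: DiscreteEnsemble) -> float:
    """Mean per-step log2 likelihood ratio against the uniform-emission null.

    Per trajectory of length n: ``(1/n) * (log2 p(y_{1:n}) + n * log2 K_E)``.  The
    additive ``n log2 K_E`` counteracts the inverse decay of the trajectory
    probability with alphabet size per step; a model identical to the independent
    uniform null scores exactly 0.
    """
    lp = prefix_log_probs_matrix(model, test.states)[:, -1]
    n = test.n_timepoints
    return float(np.mean((lp + n * np.log2(test.n_symbols)) / n))


def train_test_split(ensemble, n_test: int = 30, seed: int = 0):
    """Seeded disjoint split into (train, test); the union is the original ensemble."""
    m = ensemble.n_cells
    if not 0 < n_test < m:
        raise EvaluationError(f"n_test must be in (0, {m}), got {n_test}")
    perm = np.random.default_rng(seed).permutation(m)
    return subset_rows(ensemble, perm[n_test:]), subset_rows(ensemble, perm[:n_test])


def split_half_overfit_check(
    ensembles: list[DiscreteEnsemble], config: ModelConfig, seed: int = 0,
    tol: float = 1e-6,
) -> tuple[float, dict[str, float]]:
    """Mean maximum dMI between random equal halves of each condition's ensemble.

    Per condition: seeded bipartition, one model fitted per half at the configured
    state counts, then the maximum dMI at the final timepoint treating the halves as
    two pseudo-conditions.  Near-zero mean: the configuration does not overfit;
    elevated mean: the models resolve sampling noise as if it were stimulus identity.
    """
    from .dmi import maximize_dmi, score_conditions

    rng = np.random.default_rng(seed)
    per_condition: dict[str, float] = {}
    for ens in ensembles:
        m = ens.n_cells
        if m < 4:
            raise EvaluationError(
                f"condition {ens.condition_label!r} has only {m} trajectories; "
                "need >= 4 for a split-half check"
            )
        perm = rng.permutation(m)
        half = m // 2
        a = subset_rows(ens, perm[:half])
        b = subset_rows(ens, perm[half: 2 * half])
        seeds = rng.integers(2**31, size=2)
        model_a = config.fit(a, seed=int(seeds[0]))
        model_b = config.fit(b, seed=int(seeds[1]))
        a2 = DiscreteEnsemble("half_a", a.states, a.n_symbols, a.scheme_id)
        b2 = DiscreteEnsemble("half_b", b.states, b.n_symbols, b.scheme_id)
        scores = score_conditions([model_a, model_b], [a2, b2])
        I, _ = maximize_dmi(scores, scores.n_timepoints, tol=tol)
        per_condition[ens.condition_label] = I
    mean = float(np.mean(list(per_condition.values())))
    return mean, per_condition


@dataclass
class EvaluationReport:
    """Training-performance summary for one condition's fitted model."""

    condition_label: str
    relative_kl: np.ndarray
    relative_kl_mean: float
    false_knn_prob: float
    false_knn_per_k: dict[int, float]
    rescaled_ll: float
    split_half_dmi: float
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition_label": self.condition_label,
            "relative_kl_mean": float(self.relative_kl_mean),
            "relative_kl": [float(v) for v in self.relative_kl],
            "false_knn_prob": float(self.false_knn_prob),
            "false_knn_per_k": {int(k): float(v) for k, v in self.false_knn_per_k.items()},
            "rescaled_ll": float(self.rescaled_ll),
            "split_half_dmi": float(self.split_half_dmi),
            "config": self.config,
        }


def evaluate_condition(
    ensemble: DiscreteEnsemble,
    config: ModelConfig,
    seed: int = 0,
    n_test: int = 30,
    k_values: tuple[int, ...] = (1, 5, 10),
) -> EvaluationReport:
    """Full training-performance evaluation for one condition.

    Fits on a train split (held-out ``n_test`` trajectories), samples a synthetic
    ensemble of matching size from the fitted model, and computes all three quality
    measures plus the per-condition split-half dMI.
    """
    rng = np.random.default_rng(seed)
    train, test = train_test_split(ensemble, n_test=n_test, seed=int(rng.integers(2**31)))
    model = config.fit(train, seed=int(rng.integers(2**31)))
    sampled = sample_model(
        model, n_traj=ensemble.n_cells, length=ensemble.n_timepoints,
        seed=int(rng.integers(2**31)), condition_label=f"{ensemble.condition_label}_sample",
        scheme_id=ensemble.scheme_id,
    )
    ratios, kl_mean = relative_kl_per_timepoint(ensemble, sampled)
    knn_p, per_k = false_knn_probability(
        ensemble, sampled, k_values=k_values, seed=int(rng.integers(2**31))
    )
    rll = rescaled_log_likelihood(model, test)
    sh_mean, _ = split_half_overfit_check([ensemble], config, seed=int(rng.integers(2**31)))
    return EvaluationReport(
        condition_label=ensemble.condition_label,
        relative_kl=ratios,
        relative_kl_mean=kl_mean,
        false_knn_prob=knn_p,
        false_knn_per_k=per_k,
        rescaled_ll=rll,
        split_half_dmi=sh_mean,
        config={
            "family": config.family,
            "n_hidden": config.resolve_hidden(ensemble.n_symbols),
            "n_symbols": ensemble.n_symbols,
            "k_values": list(k_values),
            "n_test": n_test,
            "seed": seed,
        },
    )
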