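# Methods

## The estimand

`trajdmi` estimates how much information about stimulus identity is carried by the
*full time course* of a single-cell signaling response, and how that information
accumulates over time.  Given M stimulus conditions, each with an ensemble of
measured trajectories, the mutual information between the stimulus label S and the
response trajectory R up to timepoint n is

    I(R_{1:n}; S) = H(R_{1:n}) − H(R_{1:n} | S),

the difference between the unconditional and conditional trajectory entropies.  The
entropy of a *single* trajectory is −log2 p(y_{1:n}) (bits), where p is the
probability assigned by a generative model of the ensemble; entropies of the
response are plug-in averages of these per-trajectory quantities over the measured
trajectories:

    H(R_{1:n}|S)  = − Σ_i q_i (1/m_i) Σ_j log2 p(y^{i,j}_{1:n} | S=i)
    H(R_{1:n})    = − Σ_i q_i (1/m_i) Σ_j log2 Σ_k q_k p(y^{i,j}_{1:n} | S=k)

with m_i trajectories in condition i and stimulus weights q on the probability
simplex.  The *maximum* dMI maximizes I over q at each cumulative timepoint
n = 1, 2, …, N; it is a capacity-style summary of how distinguishable the supplied
condition set is from the dynamics alone, bounded above by log2 M.  We make no
claim about the capacity over stimuli that were not supplied.

The name "dynamical" is earned through the model: trajectory probabilities come
from a fitted stochastic *dynamical* model, so permuting the order of timepoints
changes the estimate — unlike density estimates over unordered response vectors.

## Models and fitting

Continuous trajectories are discretized into a common emission alphabet of K_E
symbols using **one binning scheme fitted on data pooled across all conditions**.
Pooling is not cosmetic: the unconditional entropy mixes likelihoods of the same
trajectory under different conditions' models, which is only meaningful on a shared
alphabet.  Quantile bins are the default (near-equal occupancy conditions the count
matrices well); equal-width bins are available, and are also the automatic fallback
when ties (e.g. an atom at the detection floor of rectified, baseline-subtracted
signals) collapse the quantile edges.  Bins are half-open with ties going up, the
last bin closed, and out-of-range values clamped — a model trained on one data
split can always score another split.

Two model families are provided, both with **column-stochastic** matrices (columns
index the source state):

* **Time-inhomogeneous Markov model** — one K_E × K_E transition matrix per
  consecutive timepoint pair, estimated by transition counts with a pseudocount
  (default 0.5 per cell, Jeffreys-style) and column normalization.  Flexible and
  good at synchronized features, but with N−1 matrices it is data-hungry and prone
  to overfitting.
* **Hidden Markov model** — K hidden states, a single transition matrix T and
  emission matrix E, fitted by Baum–Welch EM over all trajectories jointly.  The
  homogeneous hidden chain captures history dependence (oscillations at variable
  frequency) with only two matrices.  Defaults: hidden:emission state ratio 2:1,
  5 random restarts, relative log-likelihood tolerance 1e-6, at most 500
  iterations.  All restarts are seeded; the best final likelihood wins.  EM runs
  unfloored (so the monotone-likelihood property holds exactly, which the tests
  assert); after EM the emission matrix is floored at 1e-6 and renormalized so that
  no symbol has exactly zero likelihood under any condition's model — required for
  finite cross-condition scores.  The floor is the minimal intervention that keeps
  the mixture in H(R) well defined; its size is far below any per-step likelihood
  the data support, so self-scores are unaffected at the reported precision.

Prefix log-probabilities log2 p(y_{1:n}) for n = 1..N come from the forward
recursion p(y_{1:n}, x_n) = E(y_n|x_n) Σ T(x_n|x_{n−1}) p(y_{1:n−1}, x_{n−1}) with
per-step scaling, so trajectories of hundreds of timepoints do not underflow; the
scaled recursion is tested against exhaustive hidden-path enumeration to 1e-10.

## Maximization over stimulus weights

The plug-in estimate I(q) = Σ_i q_i Σ_j w_ij [S_iji − log2 Σ_k q_k 2^{S_ijk}]
(S = log2 scores, w_ij = 1/m_i) is concave in q.  It is maximized by projected
gradient ascent on the simplex with backtracking line search, starting from
uniform q (so the maximized value can never fall below the uniform-weight dMI),
converging when an accepted step improves I by less than 1e-6 bits (cap 10,000
iterations; non-convergence raises an error carrying the best iterate).  The same
optimizer drives the single-timepoint baseline, where the per-condition symbol
distributions at one column form a discrete memoryless channel; tests pin the
optimizer against a 1e-3-step grid search and a Blahut–Arimoto iteration,
including the Z-channel with closed-form capacity log2(5/4).

Mixtures Σ_k q_k p(·|k) are evaluated by log-sum-exp on the log2 scores; exact
zero weights are dropped (0·log 0 = 0).  Finite-sample estimates can dip
microscopically below zero; values are clipped at 0 with the raw value logged when
below −1e-9.  The cumulative curve re-optimizes q independently at each n (the
per-timepoint reading of the maximization); it is *not* forced to be monotone in
n — genuine dips occur when an intermediate response phase is less
condition-specific.

## Model-quality metrics and overfitting

* **Relative KL-divergence**: per-timepoint KL(data ‖ model-sample) divided by the
  data marginal's entropy, base 2, both marginals pseudocounted (0.5/symbol);
  averaged along the timecourse.  Below ~0.1 indicates the model reproduces the
  marginal statistics to within a tenth of their information content.
* **False k-NN probability**: model-sampled and measured trajectories are mixed;
  for each sampled trajectory the number of cross-ensemble members among its k
  nearest Euclidean neighbors (full-length vectors, self excluded) is binomially
  fitted (MLE p̂ = mean count / k, averaged over k ∈ {1, 5, 10} by default).  0.5
  is perfect mixing; values near 0 or 1 expose distributional mismatch.
* **Rescaled log-likelihood**: on a held-out test split (default 30 trajectories),
  (1/n)(log2 p(y_{1:n}) + n log2 K_E) averaged over test trajectories — the
  per-step log-likelihood ratio against an independent-uniform null.  The additive
  term counteracts the per-step decay of trajectory probability with alphabet
  size; the null model scores exactly 0 and deterministic self-scoring log2 K_E
  (both asserted).
* **Split-half overfitting check**: per condition, a seeded equal bipartition, one
  model per half, then the maximum dMI between the halves as two pseudo-conditions
  at the final timepoint.  Both halves obey the same law, so the true MI is zero;
  the measured value is the estimator's optimism at the configured state counts.
  Near-zero means trustworthy dMI values; the workflow flags configurations above
  0.1 bits.  This bias shrinks with trajectories per condition at fixed state
  counts (asserted at two sample sizes) and explodes when many states meet few
  trajectories.

## Synthetic data: what it emulates, what it does not

The **toy hidden-Markov generator** draws M ground-truth HMMs whose parameters
interpolate between one shared model (separation 0) and condition-private models
whose emissions live in disjoint blocks of ⌊K_E/M⌋ symbols (separation 1).  At full
separation the maximum dMI must saturate at log2 M bits — the key self-contained
validation of the whole pipeline (1 bit for M=2, 2 bits for M=4).  At separation 0
the dMI must vanish.  The generator returns the ground-truth models, enabling
parameter-recovery tests of Baum–Welch.

The **NF-κB-like generator** produces damped rectified sinusoids (default period
18 timepoints = 1.5 h at a 5-min interval, within the 1–2 h range of the IκBα
negative-feedback clock) or saturating pulses, with lognormal per-cell amplitude
scales, optional per-cell phase jitter, additive Gaussian noise, and clipping at
zero.  `phase_shifted_pair` yields two ensembles sharing cell scales and jitters
and differing only by a waveform phase shift — the construct behind the
permutation control: applying one random column permutation to *all* conditions
preserves every per-timepoint marginal exactly but destroys temporal ordering, so
estimators that ignore ordering are unaffected while the dMI drops.

These generators emulate amplitude heterogeneity, oscillation, damping, duration
and measurement noise — not receptor-level kinetics, dose–response families,
stimulus-specific noise structure, or correlated technical artifacts of imaging
pipelines.  Passing tests therefore demonstrate the estimator's correctness and
calibration under controlled heterogeneity, not the biological conclusions one
would draw from any particular measured dataset.

## Problem sizes and numerical choices

Desk-scale study conditions used throughout the tests and the acceptance script:
toy saturation at 200 trajectories × 60 timepoints per condition; false-k-NN
self-consistency at two independent 300 × 100 ensembles; Baum–Welch recovery at
500 × 150 from a 2-hidden/2-symbol truth; split-half regimes at 400 (modest
states, hidden count matched to the generator's 4) vs 40 trajectories (inflated,
32 hidden states); multi-condition bound checks on a 13-condition synthetic panel
with the Markov family.  The default 2:1 hidden:emission ratio is overridable;
small unit tests use 1–8 states where enumeration oracles are feasible (K ≤ 3,
n ≤ 6).

Degenerate inputs: constant-valued data fall back to unit-width equal bins with a
warning; unvisited source states get uniform transition columns; symbols absent
from training data sit at the emission floor; zero-probability steps under a
pseudocount-free Markov model yield −∞ prefixes with a warning rather than an
exception.

## Known limitations

* The dMI is a plug-in estimate evaluated on the training ensembles; its optimism
  is exactly what the split-half protocol measures.  Values from overfitted
  configurations are upper-biased — consult the split-half output before trusting
  absolute numbers.
* The emission floor (and Markov pseudocount) bound how negative cross-condition
  log-likelihoods can get; with fully disjoint ensembles the dMI therefore
  saturates slightly below the ideal rather than diverging — invisible at the
  reported precision but present in principle.
* With very few conditions (M = 2) the log2 M ceiling is close to the estimator's
  finite-sample optimism for rich models on structured data; controls such as the
  timepoint-shuffle comparison need ensembles large enough (hundreds of cells) and
  state counts modest enough that the optimism stays well below the effect being
  demonstrated.
* Per-condition models are fitted independently; shared structure across
  conditions (e.g. a common early response) is not pooled.
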